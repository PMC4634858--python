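"""Gene-protein matching, concordance, overlap, and cross-study comparison.

Proteins quantified by the rollup are matched to array probes through a
many-to-many mapping table; when a protein has several probes the one
with the highest average intensity is used as the gene expression.
Concordance is reported globally (all gene/protein points pooled) and per
matched pair (one correlation across samples per protein), with counts of
pairs passing P < 0.05 and R > 0.5.  Set-overlap machinery supports
Venn-style comparisons of peptide, protein and differential inventories
across studies, including direction-of-change agreement of shared
differential calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SampleDesign
from .io import strip_modifications
from .peptides import filter_peptides, log2_transform
from .rollup import build_peptide_protein_map, rollup_proteins
from .stats import CorrStat, correlation, rank_sum_test, differential_table, \
    call_significant

__all__ = [
    "MatchedPairs",
    "match_probes_to_proteins",
    "global_concordance",
    "per_pair_concordance",
    "ConcordanceReport",
    "OverlapReport",
    "overlap_sets",
    "Study",
    "cross_study_compare",
]


@dataclass
class MatchedPairs:
    """One chosen probe per protein, with aligned profile matrices."""

    pairs: pd.DataFrame       # index protein, column probe_id
    gene: pd.DataFrame        # proteins x samples (chosen probe values)
    protein: pd.DataFrame     # proteins x samples

    def __len__(self) -> int:
        return len(self.pairs)


def match_probes_to_proteins(exprs: pd.DataFrame, mapping: pd.DataFrame,
                             proteins: pd.DataFrame) -> MatchedPairs:
    """Restrict to proteins measured on both platforms and pick one probe each.

    For a protein with several mapped probes the probe with the highest
    mean over non-missing values wins; ties go to the lexicographically
    smallest probe id.  Proteins without any mapped, measured probe are
    excluded (intersection rule).  An empty intersection is an error.
    """
    shared_samples = [s for s in proteins.columns if s in exprs.columns]
    if not shared_samples:
        raise ValueError("no shared samples between expression and protein matrices")
    m = mapping[mapping["probe_id"].isin(exprs.index) &
                mapping["protein_id"].isin(proteins.index)]
    if m.empty:
        raise ValueError("no protein has a measured probe (empty intersection)")
    probe_means = exprs.loc[:, shared_samples].mean(axis=1, skipna=True)

    chosen: dict[str, str] = {}
    for prot, grp in m.groupby("protein_id", sort=True):
        probes = sorted(grp["probe_id"])
        best = max(probes, key=lambda p: (probe_means.get(p, -np.inf), ))
        # max() keeps the first maximum; sorted() order makes that the
        # lexicographically smallest probe on ties
        chosen[prot] = best
    pairs = pd.Series(chosen, name="probe_id").sort_index()
    pairs.index.name = "protein"
    gene = exprs.loc[pairs.to_numpy(), shared_samples].copy()
    gene.index = pairs.index
    prot = proteins.loc[pairs.index, shared_samples].copy()
    return MatchedPairs(pairs.to_frame(), gene, prot)


def global_concordance(pairs: MatchedPairs) -> dict[str, CorrStat]:
    """Pool all (gene value, protein value) points and correlate.

    Returns Pearson and Spearman statistics over the pooled cloud (the
    "all protein expressions vs all gene expressions" view).
    """
    x = pairs.gene.to_numpy(dtype=float).ravel()
    y = pairs.protein.to_numpy(dtype=float).ravel()
    return {m: correlation(x, y, method=m) for m in ("pearson", "spearman")}


@dataclass
class ConcordanceReport:
    """Per-pair gene-protein correlations and summary counts."""

    per_pair: pd.DataFrame
    mean_r: dict[str, float]
    n_significant: dict[str, int]
    n_undefined: int
    p_threshold: float
    r_threshold: float

    def to_dict(self) -> dict:
        return {
            "n_pairs": int(len(self.per_pair)),
            "mean_r": {k: float(v) for k, v in self.mean_r.items()},
            "n_significant": {k: int(v) for k, v in self.n_significant.items()},
            "n_undefined": int(self.n_undefined),
            "p_threshold": self.p_threshold,
            "r_threshold": self.r_threshold,
        }


def per_pair_concordance(pairs: MatchedPairs, p_threshold: float = 0.05,
                         r_threshold: float = 0.5) -> ConcordanceReport:
    """Correlate each protein's profile with its gene's profile across samples.

    The mean correlation includes every defined value, positive and
    negative.  Pairs with a constant profile on either side are undefined
    and excluded from the mean, with their count recorded.  A pair is
    counted significant when p < ``p_threshold`` and r > ``r_threshold``
    (both strict), per method.
    """
    rows = []
    for prot in pairs.gene.index:
        g = pairs.gene.loc[prot].to_numpy(dtype=float)
        p = pairs.protein.loc[prot].to_numpy(dtype=float)
        pe = correlation(g, p, "pearson")
        sp = correlation(g, p, "spearman")
        rows.append((prot, pe.r, pe.p, sp.r, sp.p, pe.n, pe.undefined or sp.undefined))
    df = pd.DataFrame(rows, columns=["protein", "r_pearson", "p_pearson",
                                     "r_spearman", "p_spearman", "n",
                                     "undefined"]).set_index("protein")
    defined = df[~df["undefined"]]
    mean_r = {
        "pearson": float(defined["r_pearson"].mean()) if len(defined) else np.nan,
        "spearman": float(defined["r_spearman"].mean()) if len(defined) else np.nan,
    }
    n_sig = {
        "pearson": int(((defined["p_pearson"] < p_threshold) &
                        (defined["r_pearson"] > r_threshold)).sum()),
        "spearman": int(((defined["p_spearman"] < p_threshold) &
                         (defined["r_spearman"] > r_threshold)).sum()),
    }
    return ConcordanceReport(df, mean_r, n_sig, int(df["undefined"].sum()),
                             p_threshold, r_threshold)


@dataclass
class OverlapReport:
    """Venn-style region counts for 2 or 3 labeled sets."""

    set_names: list[str]
    regions: dict[tuple[str, ...], int]
    union_size: int
    shared_all: int
    same_direction: int | None = None
    opposite_direction: int | None = None

    def to_dict(self) -> dict:
        d = {
            "set_names": list(self.set_names),
            "regions": {"&".join(k): v for k, v in self.regions.items()},
            "union_size": self.union_size,
            "shared_all": self.shared_all,
        }
        if self.same_direction is not None:
            d["same_direction"] = self.same_direction
            d["opposite_direction"] = self.opposite_direction
        return d


def overlap_sets(sets: dict[str, set],
                 signs: dict[str, dict] | None = None) -> OverlapReport:
    """Exclusive-region counts for 2 or 3 labeled id sets.

    Each element of the union is assigned to exactly one region (the
    subset of sets containing it), so region counts sum to the union size
    by construction.  When ``signs`` maps each set name to per-id
    log2 fold-change signs, the ids shared by *all* sets are split into
    same-direction (all signs agree) and opposite counts.
    """
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("overlap_sets supports 2 or 3 sets")
    union = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for element in union:
        member = tuple(n for n in names if element in sets[n])
        regions[member] = regions.get(member, 0) + 1
    # make every possible region explicit
    from itertools import combinations
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            regions.setdefault(combo, 0)
    shared_all = regions[tuple(names)]
    same = opp = None
    if signs is not None:
        core = set.intersection(*sets.values())
        same = opp = 0
        for element in core:
            ss = {np.sign(signs[n][element]) for n in names}
            if len(ss) == 1:
                same += 1
            else:
                opp += 1
    return OverlapReport(names, regions, len(union), shared_all, same, opp)


@dataclass
class Study:
    """One proteomic study: its peptide table, design, and thresholds."""

    name: str
    peptides: pd.DataFrame
    design: SampleDesign
    pep_threshold: float = 0.1


def _study_summary(study: Study, p_thresholds=(0.05, 0.01, 0.001),
                   fc_linear_threshold: float = 1.5) -> dict:
    filtered, report = filter_peptides(study.peptides, study.design,
                                       study.pep_threshold)
    mat = log2_transform(filtered, study.design)
    pmap = build_peptide_protein_map(filtered)
    prot, meta = rollup_proteins(mat, pmap)
    diff = differential_table(prot, study.design)

    samples = list(study.design.sample_ids)
    intens = study.peptides[samples]
    n_cells = intens.size
    n_missing = int(intens.isna().to_numpy().sum())
    de_counts = {f"p<{t:g}": int((diff["p"] < t).sum()) for t in p_thresholds}
    called = call_significant(diff, p_thresholds[0], fc_linear_threshold,
                              use_fc=True)
    de_counts[f"p<{p_thresholds[0]:g}_and_fc"] = int(called["called"].sum())

    return {
        "name": study.name,
        "n_peptides": int(len(study.peptides)),
        "n_peptides_retained": report.retained,
        "missing_intensities": n_missing,
        "missing_fraction": n_missing / n_cells if n_cells else np.nan,
        "mean_peptide_length": float(study.peptides["length"].mean()),
        "mean_pep": float(study.peptides["pep"].mean()),
        "n_proteins": int(len(prot)),
        "peptides_per_protein": (report.retained / len(prot)) if len(prot) else np.nan,
        "single_peptide_proteins": int(meta["single_peptide_flag"].sum()),
        "de_counts": de_counts,
        "_diff": diff,
        "_filtered": filtered,
        "_matrix": mat,
    }


def cross_study_compare(studies: list[Study], p_threshold: float = 0.05,
                        fc_linear_threshold: float = 1.5) -> dict:
    """Summary-statistics block per study plus all pairwise comparisons.

    Per study: peptide/protein inventory sizes, missingness, mean peptide
    length, peptides per protein, single-peptide-protein count, and
    differential counts at nested P thresholds with and without the
    fold-change filter.  Per pair of studies: stripped-sequence peptide
    overlap (uppercase, modifications removed, I and L distinct), Pearson
    and Spearman correlation of mean log2 intensities over shared
    peptides, a rank-sum test of the peptide-length distributions, and
    differential-call overlap with direction agreement.
    """
    if len(studies) < 2:
        raise ValueError("cross_study_compare needs at least two studies")
    summaries = [_study_summary(s, (p_threshold, 0.01, 0.001),
                                fc_linear_threshold) for s in studies]

    pairwise = []
    for i in range(len(studies)):
        for j in range(i + 1, len(studies)):
            a, b = summaries[i], summaries[j]
            seqs_a = {strip_modifications(s) for s in a["_filtered"]["sequence"]}
            seqs_b = {strip_modifications(s) for s in b["_filtered"]["sequence"]}
            shared = sorted(seqs_a & seqs_b)

            mean_a = a["_matrix"].mean(axis=1, skipna=True)
            mean_a.index = [strip_modifications(s) for s in mean_a.index]
            mean_a = mean_a.groupby(level=0).mean()  # merge modified forms
            mean_b = b["_matrix"].mean(axis=1, skipna=True)
            mean_b.index = [strip_modifications(s) for s in mean_b.index]
            mean_b = mean_b.groupby(level=0).mean()
            xa = mean_a.reindex(shared).to_numpy(dtype=float)
            xb = mean_b.reindex(shared).to_numpy(dtype=float)
            corr_p = correlation(xa, xb, "pearson")
            corr_s = correlation(xa, xb, "spearman")

            lengths = rank_sum_test(studies[i].peptides["length"],
                                    studies[j].peptides["length"])

            da = call_significant(a["_diff"], p_threshold, fc_linear_threshold)
            db = call_significant(b["_diff"], p_threshold, fc_linear_threshold)
            set_a = set(da.index[da["called"]])
            set_b = set(db.index[db["called"]])
            signs = {
                a["name"]: da["log2fc"].to_dict(),
                b["name"]: db["log2fc"].to_dict(),
            }
            overlap = overlap_sets({a["name"]: set_a, b["name"]: set_b}, signs)

            pairwise.append({
                "studies": (a["name"], b["name"]),
                "shared_peptides": len(shared),
                "mean_intensity_pearson_r": corr_p.r,
                "mean_intensity_pearson_p": corr_p.p,
                "mean_intensity_spearman_r": corr_s.r,
                "mean_intensity_spearman_p": corr_s.p,
                "peptide_length_ranksum_p": lengths.p,
                "de_overlap": overlap.to_dict(),
            })

    per_study = []
    for s in summaries:
        per_study.append({k: v for k, v in s.items() if not k.startswith("_")})
    return {"studies": per_study, "pairwise": pairwise}
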