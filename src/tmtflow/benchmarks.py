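"""Self-validation benchmarks: oracle agreement and recovery experiments.

Each function runs one end-to-end check of the pipeline against an
independent oracle (a directly coded formula, an exhaustive enumeration,
a closed-form construction, or a direct Monte-Carlo of the generative
model) and returns the measured quantities.  The statistical recovery
experiments use a controlled configuration — fixed peptide count per
protein and no shared peptides — so that channel noise and missingness
are the only stochastic inputs and the expected recovery error has a
known scale; the robustness of the rollup to shared peptides and
heavy-tailed peptide counts is exercised separately in the unit suite.

All functions are deterministic given their seed.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import RunConfig, SampleDesign
from .peptides import filter_peptides, log2_transform, select_reference_sample, \
    normalize_to_reference
from .rollup import build_peptide_protein_map, rollup_proteins, tukey_biweight
from .stats import welch_t_test, differential_table, call_significant, \
    hierarchical_cluster, rank_sum_test
from .integrate import match_probes_to_proteins, per_pair_concordance, \
    overlap_sets
from .simulate import SimParams, generate_ground_truth, simulate_peptide_table, \
    simulate_microarray, missingness_for_rate
from .pipeline import run_pipeline

__all__ = [
    "biweight_oracle",
    "biweight_agreement",
    "welch_agreement",
    "type_i_error_rate",
    "recovery_params",
    "parameter_recovery",
    "normalization_recovery",
    "filter_benchmark_table",
    "filter_benchmark_counts",
    "clustering_recovery",
    "concordance_recovery",
    "ranksum_agreement",
    "set_logic_checks",
]


# ------------------------------------------------- biweight oracle agreement

def biweight_oracle(values, c: float = 5.0, epsilon: float = 1e-4) -> float:
    """Direct, independent evaluation of the one-step biweight formula."""
    x = [float(v) for v in values if not np.isnan(v)]
    m = float(np.median(x))
    s = float(np.median([abs(v - m) for v in x]))
    num = den = 0.0
    for v in x:
        u = (v - m) / (c * s + epsilon)
        if abs(u) < 1.0:
            w = (1.0 - u * u) ** 2
            num += w * v
            den += w
    return num / den if den > 0 else m


def biweight_agreement(seed: int, n_vectors: int = 1000) -> dict:
    """Max |implementation - oracle| over random vectors with outliers."""
    rng = np.random.default_rng([seed, 101])
    worst = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 51))
        x = rng.normal(rng.uniform(-20, 20), rng.uniform(0.1, 3), n)
        if n >= 3 and rng.random() < 0.6:
            k = int(rng.integers(1, max(2, n // 4)))
            idx = rng.choice(n, k, replace=False)
            x[idx] += rng.choice([-1, 1], k) * rng.uniform(5, 100, k)
        worst = max(worst, abs(tukey_biweight(x) - biweight_oracle(x)))
    return {"max_abs_diff": worst, "n": n_vectors}


# ---------------------------------------------------- Welch oracle agreement

def welch_agreement(seed: int, n_cases: int = 1000) -> dict:
    """Agreement of t, df and p with the fixed closed form and scipy."""
    fixed = welch_t_test([10, 11, 12], [13, 14, 15])
    err_fixed = max(abs(fixed.statistic - (-3.0 / np.sqrt(2.0 / 3.0))),
                    abs(fixed.df - 4.0))
    rng = np.random.default_rng([seed, 102])
    worst = err_fixed
    for _ in range(n_cases):
        nx, ny = rng.integers(2, 15, 2)
        x = rng.normal(0, rng.uniform(0.2, 4), nx)
        y = rng.normal(rng.uniform(-3, 3), rng.uniform(0.2, 4), ny)
        mine = welch_t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        worst = max(worst, abs(mine.statistic - ref.statistic),
                    abs(mine.df - ref.df), abs(mine.p - ref.pvalue))
    return {"max_abs_diff": worst, "n": n_cases}


# --------------------------------------------------------- null type-I error

def type_i_error_rate(seed: int, n_features: int = 2000,
                      n_per_group: int = 3) -> dict:
    """Fraction of null features with p < 0.05 (no effect, normal noise)."""
    rng = np.random.default_rng([seed, 103])
    data = rng.normal(10.0, 1.0, (n_features, 2 * n_per_group))
    n_sig = 0
    for row in data:
        if welch_t_test(row[:n_per_group], row[n_per_group:]).p < 0.05:
            n_sig += 1
    return {"rate": n_sig / n_features, "n": n_features}


# ---------------------------- differential recovery and clustering recovery

def recovery_params(seed: int, **overrides) -> SimParams:
    """Controlled recovery configuration: channel noise and reporter-style
    missingness are the only stochastic inputs (fixed 7 peptides per
    protein, no shared peptides, no decoys/contaminants)."""
    base = dict(n_proteins=300, frac_de=0.1, de_log2fc=2.0,
                channel_noise_sd=0.25, missingness=missingness_for_rate(0.001),
                peptides_per_protein=(7.0, 0.0), frac_shared_peptides=0.0,
                peptide_efficiency_sd=0.0, frac_decoy=0.0,
                frac_contaminant=0.0, seed=seed)
    base.update(overrides)
    return SimParams(**base).validate()


def parameter_recovery(seed: int) -> dict:
    """Run the full pipeline on the controlled configuration and score the
    differential calls against ground truth."""
    truth = generate_ground_truth(recovery_params(seed))
    table = simulate_peptide_table(truth)
    result = run_pipeline(RunConfig(seed=seed), truth.design, table)
    diff = result.differential_proteins

    de = truth.proteins[truth.proteins["is_de"]]
    called = diff.loc[de.index, "called"]
    est_fc = diff.loc[de.index, "log2fc"]
    true_fc = de["delta"]
    errors = (est_fc - true_fc).abs()
    signs_ok = (np.sign(est_fc) == np.sign(true_fc))
    fdr_denom = int(diff["called"].sum())
    return {
        "n_true_de": int(len(de)),
        "sensitivity": float(called.mean()),
        "max_abs_log2fc_error": float(errors.max()),
        "sign_agreement": float(signs_ok.mean()),
        "n_called_total": fdr_denom,
    }


def clustering_recovery(seed: int, n_replicates: int = 100) -> dict:
    """Fraction of replicates whose 2-cut equals the ADC/SCC partition."""
    rng = np.random.default_rng([seed, 107])
    n_correct = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        truth = generate_ground_truth(recovery_params(rep_seed))
        table = simulate_peptide_table(truth)
        kept, _ = filter_peptides(table, truth.design)
        mat = log2_transform(kept, truth.design)
        pmap = build_peptide_protein_map(kept)
        prot, _ = rollup_proteins(mat, pmap)
        labels = hierarchical_cluster(prot).labels
        groups = dict(zip(truth.design.sample_ids, truth.design.groups))
        split: dict[int, set] = {}
        for s, lab in labels.items():
            split.setdefault(lab, set()).add(groups[s])
        if all(len(g) == 1 for g in split.values()) and len(split) == 2:
            n_correct += 1
    return {"n_correct": n_correct, "n_replicates": n_replicates,
            "rate": n_correct / n_replicates}


# --------------------------------------------- normalization offset recovery

def normalization_recovery(seed: int, n_features: int = 1000,
                           contamination: float = 0.10) -> dict:
    """Inject per-sample log2 offsets up to ±2 plus 10% perturbed features
    and measure how well the offsets are recovered."""
    rng = np.random.default_rng([seed, 105])
    samples = [f"s{i}" for i in range(6)]
    base = rng.normal(12.0, 1.5, n_features)
    offsets = np.array([0.0, 2.0, -2.0, 1.0, -1.0, 0.5])
    m = pd.DataFrame({s: base + off for s, off in zip(samples, offsets)},
                     index=[f"f{i}" for i in range(n_features)])
    # per-sample independent measurement noise + contaminated features
    for j, s in enumerate(samples):
        m[s] += rng.normal(0.0, 0.05, n_features)
        bad = rng.choice(n_features, int(contamination * n_features),
                         replace=False)
        m.iloc[bad, j] += rng.choice([-5.0, 5.0], bad.size)
    ref = select_reference_sample(m)
    before = m[ref].to_numpy().copy()
    normalized, rec = normalize_to_reference(m, ref)
    expected = offsets - offsets[samples.index(ref)]
    err = float(np.max(np.abs(rec.to_numpy() - expected)))
    ref_identical = bool(np.array_equal(normalized[ref].to_numpy(), before))
    return {"max_offset_error": err, "reference_bit_identical": ref_identical,
            "n": n_features}


# ----------------------------------------------------- QC filter fixture

def filter_benchmark_table(design: SampleDesign) -> pd.DataFrame:
    """Ten hand-built rows: 2 high-PEP, 1 reverse, 1 contaminant,
    2 over-missing, and 4 clean rows sitting on both filter boundaries."""
    samples = list(design.sample_ids)

    def row(seq, pep=0.01, reverse=False, contaminant=False, n_missing=0):
        intens = [500.0 * (i + 2) for i in range(len(samples))]
        for i in range(n_missing):
            intens[i] = np.nan
        rec = dict(sequence=seq, proteins=[f"PR{seq}"], pep=pep,
                   reverse=reverse, contaminant=contaminant, length=len(seq))
        rec.update(dict(zip(samples, intens)))
        return rec

    return pd.DataFrame([
        row("QPEPA", pep=0.2),
        row("QPEPB", pep=0.5),
        row("QREV", reverse=True),
        row("QCON", contaminant=True),
        row("QMISSA", n_missing=4),
        row("QMISSB", n_missing=5),
        row("QOKA", pep=0.1),
        row("QOKB", pep=0.05),
        row("QOKC", n_missing=3),
        row("QOKD"),
    ])


def filter_benchmark_counts() -> dict:
    design = SampleDesign(
        ["ADC1", "ADC2", "ADC3", "SCC1", "SCC2", "SCC3"],
        ["126", "127", "128", "129", "130", "131"],
        ["ADC"] * 3 + ["SCC"] * 3)
    _, report = filter_peptides(filter_benchmark_table(design), design)
    return {**report.removed, "retained": report.retained}


# ----------------------------------------------- gene-protein concordance

def concordance_params(seed: int, rho: float = 0.6, n_genes: int = 500,
                       n_samples: int = 20) -> SimParams:
    return recovery_params(seed, n_proteins=n_genes, frac_de=1.0,
                           n_samples_per_group=n_samples // 2,
                           gene_protein_corr=rho,
                           n_probes_per_gene=(1.0, 0.0))


def concordance_recovery(seed: int, rho: float = 0.6, n_genes: int = 500,
                         n_samples: int = 20, n_oracle: int = 300) -> dict:
    """Mean per-pair gene-protein Pearson r from the full pipeline vs the
    99% Monte-Carlo interval of a directly coded generative oracle, plus
    the exact noise-free rho=1 limit."""
    params = concordance_params(seed, rho, n_genes, n_samples)
    truth = generate_ground_truth(params)
    table = simulate_peptide_table(truth)
    kept, _ = filter_peptides(table, truth.design)
    mat = log2_transform(kept, truth.design)
    pmap = build_peptide_protein_map(kept)
    prot, _ = rollup_proteins(mat, pmap)
    exprs, mapping = simulate_microarray(truth)
    matched = match_probes_to_proteins(exprs, mapping, prot)
    mean_r = per_pair_concordance(matched).mean_r["pearson"]

    # independent oracle: two-level standardized protein profile, protein
    # measurement noise ~ channel_sd / sqrt(n_peptides), probe = scale *
    # (rho z + sqrt(1-rho^2) eps) + array noise; per-pair Pearson r
    rng = np.random.default_rng([seed, 108])
    half = n_samples // 2
    z = np.concatenate([-np.ones(half), np.ones(half)])
    z = (z - z.mean()) / z.std()
    n_pep = int(params.peptides_per_protein[0])
    meas_sd = params.channel_noise_sd / np.sqrt(n_pep)
    means = []
    for _ in range(n_oracle):
        # per replicate, n_genes pairs; each DE protein's profile amplitude
        # is |delta|/2 around its center on the standardized pattern
        amp = params.de_log2fc / 2.0
        prot_prof = amp * z[None, :] + rng.normal(0, meas_sd, (n_genes, n_samples))
        latent = rho * z[None, :] + np.sqrt(1 - rho**2) * \
            rng.standard_normal((n_genes, n_samples))
        gene_prof = params.gene_scale * latent + \
            rng.normal(0, params.array_noise_sd, (n_genes, n_samples))
        pc = (prot_prof - prot_prof.mean(1, keepdims=True))
        gc = (gene_prof - gene_prof.mean(1, keepdims=True))
        rs = (pc * gc).sum(1) / np.sqrt((pc**2).sum(1) * (gc**2).sum(1))
        means.append(rs.mean())
    lo, hi = np.quantile(means, [0.005, 0.995])

    # exact limit: rho = 1, zero noise everywhere -> every pair r = 1
    exact_params = recovery_params(seed, n_proteins=50, frac_de=1.0,
                                   n_samples_per_group=3,
                                   gene_protein_corr=1.0, array_noise_sd=0.0,
                                   channel_noise_sd=0.0,
                                   missingness=(-np.inf, 0.0),
                                   n_probes_per_gene=(1.0, 0.0))
    t2 = generate_ground_truth(exact_params)
    tab2 = simulate_peptide_table(t2)
    kept2, _ = filter_peptides(tab2, t2.design)
    mat2 = log2_transform(kept2, t2.design)
    prot2, _ = rollup_proteins(mat2, build_peptide_protein_map(kept2))
    ex2, map2 = simulate_microarray(t2)
    exact_mean = per_pair_concordance(
        match_probes_to_proteins(ex2, map2, prot2)).mean_r["pearson"]

    return {"mean_pair_r": float(mean_r), "oracle_lo": float(lo),
            "oracle_hi": float(hi), "exact_noise_free_mean_r": float(exact_mean),
            "n_genes": n_genes, "n_samples": n_samples}


# --------------------------------------------- rank-sum approximation error

def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exhaustive-permutation two-sided Mann-Whitney p (tie-free inputs)."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = sps.rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    base = n1 * (n1 + 1) / 2.0
    observed = abs(ranks[:n1].sum() - base - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        u = ranks[list(combo)].sum() - base
        if abs(u - mu) >= observed - 1e-12:
            hits += 1
    return hits / total


def ranksum_agreement(seed: int, n_cases_per_size: int = 100) -> dict:
    """Max |normal-approximation p - exact permutation p| for 3v3..5v5."""
    rng = np.random.default_rng([seed, 109])
    worst = 0.0
    for n in (3, 4, 5):
        done = 0
        while done < n_cases_per_size:
            x = rng.normal(0, 1, n)
            y = rng.normal(rng.uniform(-1.5, 1.5), 1, n)
            if len(np.unique(np.concatenate([x, y]))) < 2 * n:
                continue  # enforce tie-free
            approx = rank_sum_test(x, y).p
            worst = max(worst, abs(approx - exact_ranksum_p(x, y)))
            done += 1
    return {"max_abs_p_diff": worst, "n": 3 * n_cases_per_size}


# ----------------------------------------------------- set-logic invariants

def set_logic_checks(seed: int, n_instances: int = 1000) -> dict:
    """Venn-region conservation and DE-threshold monotonicity violations."""
    rng = np.random.default_rng([seed, 110])
    venn_violations = 0
    half = n_instances // 2
    universe = [f"e{i}" for i in range(60)]
    for _ in range(half):
        k = int(rng.integers(2, 4))
        sets = {f"S{j}": {e for e in universe if rng.random() < rng.uniform(0.1, 0.7)}
                for j in range(k)}
        rep = overlap_sets(sets)
        if sum(rep.regions.values()) != rep.union_size:
            venn_violations += 1

    mono_violations = 0
    table = pd.DataFrame({"p": rng.uniform(0, 1, 400),
                          "log2fc": rng.normal(0, 1.5, 400)})
    for _ in range(n_instances - half):
        p1, p2 = np.sort(rng.uniform(0.001, 0.3, 2))
        f1, f2 = np.sort(rng.uniform(1.01, 3.0, 2))
        n11 = call_significant(table, p1, f2)["called"].sum()
        n12 = call_significant(table, p1, f1)["called"].sum()
        n21 = call_significant(table, p2, f2)["called"].sum()
        n22 = call_significant(table, p2, f1)["called"].sum()
        if not (n11 <= n12 <= n22 and n11 <= n21 <= n22):
            mono_violations += 1
    return {"venn_violations": venn_violations,
            "monotonicity_violations": mono_violations,
            "n": n_instances}
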