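"""Synthetic 6-plex TMT peptide tables and matched microarray data.

The generator emulates the structure of a two-histology (ADC vs SCC)
isobaric-labeling experiment with a matched expression array, with full
ground truth for recovery testing:

* Protein truth: per-protein baseline log2 abundance ~ Normal(11.4, 1.43)
  (the location and spread of log2 reporter-ion intensities typical of
  6-plex TMT tissue data); a fixed fraction of proteins carries a signed
  group effect delta (log2 units); per-sample loading offsets model
  global pipetting/labeling shifts.  The true log2 abundance of protein p
  in sample s is ``baseline_p + delta_p * 1[s in group 2] + loading_s``
  (plus optional per-sample biological noise, off by default).
* Peptides: counts per protein follow 1 + NegBin (overdispersed, so a
  realistic 15-25% of proteins are single-peptide); a shared peptide's
  linear signal is the SUM of its parents' linear abundances (reporter
  signal is additive across co-isolated origins), scaled by a per-peptide
  ionization efficiency, with Normal channel noise on the log2 scale.
  Cells go missing not-at-random via logistic(alpha - beta * log2
  intensity); decoy (reversed) and contaminant rows carry their flags and
  PEP scores drawn from the appropriate distribution.
* Microarray: each protein's gene gets >= 1 probe; the gene latent
  profile is ``rho * z_p + sqrt(1-rho^2) * z_g`` where z_p is the
  standardized true protein profile, so ``gene_protein_corr`` sets the
  latent transcript-protein correlation; probe values add an affinity
  offset and array noise.

Two missingness presets bracket the field: ``tmt_like`` (~0.1% missing,
as seen for reporter-ion quantification) and ``labelfree_like`` (~18%,
as seen for label-free peptide intensities).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SampleDesign

__all__ = [
    "SimParams",
    "GroundTruth",
    "tmt_like",
    "labelfree_like",
    "missingness_for_rate",
    "generate_ground_truth",
    "simulate_peptide_table",
    "simulate_microarray",
    "write_truth",
    "read_truth",
]


def missingness_for_rate(rate: float, beta: float = 0.5,
                         at_log2: float = 11.4) -> tuple[float, float]:
    """Logistic (alpha, beta) giving dropout probability ``rate`` at a
    typical log2 intensity ``at_log2`` (nominal; with beta > 0 the realized
    overall rate shifts slightly with the intensity spread)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return (-np.inf, beta)
    return (float(logit(rate) + beta * at_log2), beta)


@dataclass
class SimParams:
    """Parameters of the synthetic proteogenomic experiment.

    Distribution specs are ``(mean, dispersion)`` tuples for count
    variables: dispersion 0 gives the constant ``round(mean)``; dispersion
    d > 0 gives ``1 + NegBin`` with mean ``mean - 1`` and shape ``d``
    (smaller d = heavier tail, more single-peptide proteins).
    """

    n_proteins: int = 1000
    # calibrated so the REALIZED single-peptide-protein fraction (after
    # shared peptides add parents) is ~21%, typical of TMT tissue data
    peptides_per_protein: tuple[float, float] = (7.0, 0.28)
    frac_shared_peptides: float = 0.10
    frac_de: float = 0.1
    de_log2fc: float = 2.0
    protein_baseline: tuple[float, float] = (11.4, 1.43)
    peptide_efficiency_sd: float = 0.5
    channel_noise_sd: float = 0.25
    biological_sd: float = 0.0
    sample_loading_offsets: tuple[float, ...] | None = None
    missingness: tuple[float, float] = missingness_for_rate(0.001)
    frac_decoy: float = 0.01
    frac_contaminant: float = 0.01
    pep_true: tuple[float, float] = (0.5, 87.0)     # Beta(a, b), mean ~0.0057
    pep_decoy: tuple[float, float] = (2.0, 2.0)     # 0.1 + 0.9 * Beta(a, b)
    n_probes_per_gene: tuple[float, float] = (2.0, 5.0)
    gene_protein_corr: float = 0.3
    gene_scale: float = 1.0
    probe_affinity: tuple[float, float] = (8.0, 1.5)
    array_noise_sd: float = 0.25
    peptide_length: tuple[float, float] = (12.26, 3.0)  # Normal, clipped to [7, 40]
    n_samples_per_group: int = 3
    group_names: tuple[str, str] = ("ADC", "SCC")
    first_channel: int = 126
    seed: int = 0

    def validate(self) -> "SimParams":
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")
        for name in ("frac_shared_peptides", "frac_de", "frac_decoy",
                     "frac_contaminant"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("peptide_efficiency_sd", "channel_noise_sd",
                     "biological_sd", "array_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (abs(self.gene_protein_corr) <= 1.0):
            raise ValueError("gene_protein_corr must be in [-1, 1]")
        if abs(self.gene_protein_corr) == 1.0 and self.array_noise_sd == 0.0:
            pass  # exact-copy construction, explicitly allowed
        if self.sample_loading_offsets is not None and \
                len(self.sample_loading_offsets) != 2 * self.n_samples_per_group:
            raise ValueError("sample_loading_offsets must have one entry per sample")
        if self.peptides_per_protein[0] < 1:
            raise ValueError("peptides_per_protein mean must be >= 1")
        return self


def tmt_like(**overrides) -> SimParams:
    """Preset emulating reporter-ion quantification (~0.1% missingness)."""
    return replace(SimParams(missingness=missingness_for_rate(0.001)),
                   **overrides).validate()


def labelfree_like(**overrides) -> SimParams:
    """Preset emulating label-free peptide intensities (~18% missingness)."""
    return replace(SimParams(missingness=missingness_for_rate(0.18)),
                   **overrides).validate()


@dataclass
class GroundTruth:
    """Everything the generator knows, for downstream recovery tests."""

    design: SampleDesign
    proteins: pd.DataFrame          # index protein: baseline, delta, is_de
    abundance: pd.DataFrame         # proteins x samples true log2 abundance
    peptides: pd.DataFrame          # sequence, parents, efficiency, pep, kind, length
    loading: pd.Series              # per-sample log2 loading offsets
    params: SimParams
    genes: pd.DataFrame | None = field(default=None)  # filled by simulate_microarray


def _count_draw(rng: np.random.Generator, spec: tuple[float, float],
                size: int, minimum: int = 1) -> np.ndarray:
    mean, disp = spec
    if disp == 0:
        return np.full(size, max(minimum, int(round(mean))), dtype=int)
    mu = max(mean - minimum, 1e-9)
    p = disp / (disp + mu)
    return minimum + rng.negative_binomial(disp, p, size=size)


def generate_ground_truth(params: SimParams) -> GroundTruth:
    """Draw the latent experiment: protein truth, peptide map, design."""
    params.validate()
    rng = np.random.default_rng([params.seed, 0])
    g1, g2 = params.group_names
    npg = params.n_samples_per_group
    sample_ids = [f"{g1}{i + 1}" for i in range(npg)] + \
                 [f"{g2}{i + 1}" for i in range(npg)]
    channels = [str(params.first_channel + i) for i in range(2 * npg)]
    design = SampleDesign(sample_ids, channels, [g1] * npg + [g2] * npg)

    n = params.n_proteins
    prot_ids = [f"P{i:05d}" for i in range(1, n + 1)]
    baseline = rng.normal(params.protein_baseline[0], params.protein_baseline[1], n)
    n_de = int(round(params.frac_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    delta = np.zeros(n)
    if n_de:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        delta[de_idx] = signs * params.de_log2fc
    proteins = pd.DataFrame({"baseline": baseline, "delta": delta,
                             "is_de": delta != 0.0},
                            index=pd.Index(prot_ids, name="protein"))

    if params.sample_loading_offsets is not None:
        loading = np.asarray(params.sample_loading_offsets, dtype=float)
    else:
        loading = np.zeros(2 * npg)
    loading = pd.Series(loading, index=sample_ids, name="loading")

    in_g2 = np.array([g == g2 for g in design.groups], dtype=float)
    abundance = baseline[:, None] + delta[:, None] * in_g2[None, :] + \
        loading.to_numpy()[None, :]
    if params.biological_sd > 0:
        abundance = abundance + rng.normal(0.0, params.biological_sd,
                                           size=abundance.shape)
    abundance = pd.DataFrame(abundance, index=proteins.index, columns=sample_ids)

    # peptide memberships
    counts = _count_draw(rng, params.peptides_per_protein, n)
    parents: list[list[str]] = []
    for i, cnt in enumerate(counts):
        parents.extend([[prot_ids[i]]] * cnt)
    n_pep = len(parents)
    n_shared = int(round(params.frac_shared_peptides * n_pep))
    if n_shared and n > 1:
        shared_idx = rng.choice(n_pep, size=n_shared, replace=False)
        for j in shared_idx:
            first = parents[j][0]
            other = prot_ids[int(rng.integers(n))]
            while other == first:
                other = prot_ids[int(rng.integers(n))]
            parents[j] = [first, other]

    a, b = params.pep_true
    pep_scores = rng.beta(a, b, size=n_pep)
    eff = rng.normal(0.0, params.peptide_efficiency_sd, size=n_pep)
    lengths = np.clip(np.round(rng.normal(*params.peptide_length, size=n_pep)),
                      7, 40).astype(int)
    records = pd.DataFrame({
        "sequence": [f"PEP{j:06d}" for j in range(1, n_pep + 1)],
        "parents": parents,
        "efficiency": eff,
        "pep": pep_scores,
        "kind": "target",
        "length": lengths,
    })

    # decoy and contaminant rows, with their own latent log2 levels
    extras = []
    da, db = params.pep_decoy
    for kind, frac, tag in (("decoy", params.frac_decoy, "REV__Q"),
                            ("contaminant", params.frac_contaminant, "CON__Q")):
        n_extra = int(round(frac * n_pep))
        if n_extra == 0:
            continue
        pep_draw = (0.1 + 0.9 * rng.beta(da, db, size=n_extra)) if kind == "decoy" \
            else rng.beta(a, b, size=n_extra)
        extras.append(pd.DataFrame({
            "sequence": [f"{kind.upper()[:3]}PEP{j:05d}" for j in range(1, n_extra + 1)],
            "parents": [[f"{tag}{j:05d}"] for j in range(1, n_extra + 1)],
            "efficiency": rng.normal(params.protein_baseline[0],
                                     params.protein_baseline[1], size=n_extra),
            "pep": pep_draw,
            "kind": kind,
            "length": np.clip(np.round(rng.normal(*params.peptide_length,
                                                  size=n_extra)), 7, 40).astype(int),
        }))
    peptides = pd.concat([records, *extras], ignore_index=True)

    return GroundTruth(design=design, proteins=proteins, abundance=abundance,
                       peptides=peptides, loading=loading, params=params)


def simulate_peptide_table(truth: GroundTruth, params: SimParams | None = None,
                           ) -> pd.DataFrame:
    """Realize a peptide table (internal format) from the ground truth.

    For a target peptide the noise-free linear intensity in sample s is
    ``2^efficiency * sum over parents of 2^abundance[parent, s]``; the
    stored value adds Normal(0, channel_noise_sd) on the log2 scale and is
    kept on the linear scale (the pipeline re-logs it).  Each cell then
    drops out independently with probability
    ``logistic(alpha - beta * log2 value)``.  Decoy/contaminant rows use
    their own latent level in ``efficiency`` and carry their flags.
    """
    params = (params or truth.params).validate()
    rng = np.random.default_rng([params.seed, 1])
    samples = list(truth.design.sample_ids)
    abund_lin = np.power(2.0, truth.abundance.to_numpy())  # proteins x samples
    prot_row = {p: i for i, p in enumerate(truth.abundance.index)}

    n_rows = len(truth.peptides)
    log2_vals = np.empty((n_rows, len(samples)))
    for j, rec in enumerate(truth.peptides.itertuples(index=False)):
        if rec.kind == "target":
            base = np.zeros(len(samples))
            for parent in rec.parents:
                base += abund_lin[prot_row[parent]]
            log2_vals[j] = np.log2(base) + rec.efficiency
        else:
            log2_vals[j] = rec.efficiency  # latent log2 level for the row
    if params.channel_noise_sd > 0:
        log2_vals = log2_vals + rng.normal(0.0, params.channel_noise_sd,
                                           size=log2_vals.shape)

    alpha, beta = params.missingness
    if np.isfinite(alpha):
        p_missing = expit(alpha - beta * log2_vals)
        drop = rng.random(size=log2_vals.shape) < p_missing
    else:
        drop = np.zeros_like(log2_vals, dtype=bool)
    linear = np.power(2.0, log2_vals)
    linear[drop] = np.nan

    table = pd.DataFrame({
        "sequence": truth.peptides["sequence"].to_numpy(),
        "proteins": truth.peptides["parents"].to_numpy(),
        "pep": truth.peptides["pep"].to_numpy(),
        "reverse": (truth.peptides["kind"] == "decoy").to_numpy(),
        "contaminant": (truth.peptides["kind"] == "contaminant").to_numpy(),
        "length": truth.peptides["length"].to_numpy(),
    })
    for k, sid in enumerate(samples):
        table[sid] = linear[:, k]
    return table


def simulate_microarray(truth: GroundTruth, params: SimParams | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Realize probe x sample expression and the probe-to-protein mapping.

    One gene per protein.  The gene latent profile is
    ``rho * z_p + sqrt(1 - rho^2) * z_g`` with z_p the standardized true
    protein log2 profile (z_p = 0 when the profile is constant, e.g. a
    non-differential protein with zero loading and biological noise — its
    transcript then carries no protein-tracking signal) and z_g iid
    standard normal per sample.  Each probe reads
    ``affinity + gene_scale * latent + Normal(0, array_noise_sd)``.

    Returns the expression matrix (log2) and the (probe_id, protein_id)
    mapping; per-gene latent parameters are recorded on
    ``truth.genes``.
    """
    params = (params or truth.params).validate()
    rng = np.random.default_rng([params.seed, 2])
    samples = list(truth.design.sample_ids)
    n_samples = len(samples)
    rho = params.gene_protein_corr

    probe_ids: list[str] = []
    probe_protein: list[str] = []
    rows: list[np.ndarray] = []
    gene_records = []
    n_probes = _count_draw(rng, params.n_probes_per_gene, len(truth.proteins))
    for i, prot in enumerate(truth.abundance.index):
        profile = truth.abundance.loc[prot].to_numpy(dtype=float)
        sd = profile.std()
        z_p = (profile - profile.mean()) / sd if sd > 0 else np.zeros(n_samples)
        z_g = rng.standard_normal(n_samples)
        latent = rho * z_p + np.sqrt(max(0.0, 1.0 - rho**2)) * z_g
        gene = f"G{i + 1:05d}"
        gene_records.append((gene, prot, sd > 0))
        for j in range(n_probes[i]):
            affinity = rng.normal(*params.probe_affinity)
            noise = rng.normal(0.0, params.array_noise_sd, size=n_samples) \
                if params.array_noise_sd > 0 else 0.0
            probe_ids.append(f"{gene}_p{j + 1}")
            probe_protein.append(prot)
            rows.append(affinity + params.gene_scale * latent + noise)

    exprs = pd.DataFrame(np.vstack(rows), columns=samples,
                         index=pd.Index(probe_ids, name="probe_id"))
    mapping = pd.DataFrame({"probe_id": probe_ids, "protein_id": probe_protein})
    truth.genes = pd.DataFrame(gene_records,
                               columns=["gene", "protein", "profile_varies"])
    return exprs, mapping


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize the per-protein truth (baseline, delta) to TSV."""
    truth.proteins.to_csv(path, sep="\t", float_format="%.10g")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df["is_de"] = df["is_de"].astype(bool)
    return df
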