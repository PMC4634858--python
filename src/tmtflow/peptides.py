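"""Peptide-level QC filtering, log2 transform, and reference normalization.

The QC filter removes, in a fixed attribution order: identifications with
posterior error probability strictly above the threshold, reversed (decoy)
sequences, contaminant peptides, and rows with more missing reporter
intensities than the larger of the two group sizes.  A row failing several
rules is counted once, under the first rule in that order, so the filter
report is deterministic and its counts conserve the input row total.

Normalization applies one global multiplicative scale (a log2 offset) per
sample, estimated against a reference sample over an iteratively refined
rank-invariant feature subset — a simple surrogate for reference-based
rank-order normalization schemes used on intensity data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import SampleDesign
from .rollup import tukey_biweight

__all__ = [
    "FilterReport",
    "filter_peptides",
    "log2_transform",
    "select_reference_sample",
    "normalize_to_reference",
]

#: Fixed attribution order for the filter report.
FILTER_RULES = ("pep", "reverse", "contaminant", "missingness")


@dataclass
class FilterReport:
    """Per-rule removal counts for one filtering pass."""

    input_rows: int
    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0
    missing_cells_before: int = 0
    missing_cells_after: int = 0

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def to_dict(self) -> dict:
        return {
            "input_rows": self.input_rows,
            "removed": dict(self.removed),
            "retained": self.retained,
            "missing_cells_before": self.missing_cells_before,
            "missing_cells_after": self.missing_cells_after,
        }


def filter_peptides(table: pd.DataFrame, design: SampleDesign,
                    pep_threshold: float = 0.1,
                    max_missing: int | None = None,
                    ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the peptide QC filters and report per-rule removal counts.

    Parameters
    ----------
    table :
        Internal peptide table (see :mod:`tmtflow.io`).
    pep_threshold :
        Rows with PEP strictly greater than this are removed.
    max_missing :
        Rows with strictly more missing intensities than this are removed.
        Defaults to the larger of the group sizes (3 for a 3 vs 3 design:
        a peptide missing in 4 of 6 channels is dropped, 3 of 6 is kept).
    """
    if max_missing is None:
        max_missing = max(design.group_sizes().values())
    samples = list(design.sample_ids)
    intens = table[samples]

    n_missing = intens.isna().sum(axis=1)
    fail_pep = table["pep"].to_numpy() > pep_threshold
    fail_rev = table["reverse"].to_numpy()
    fail_con = table["contaminant"].to_numpy()
    fail_mis = (n_missing > max_missing).to_numpy()

    reason = np.full(len(table), "", dtype=object)
    for name, mask in [("missingness", fail_mis), ("contaminant", fail_con),
                       ("reverse", fail_rev), ("pep", fail_pep)]:
        reason[mask] = name  # later assignments (earlier rules) take precedence

    keep = reason == ""
    removed = {rule: int((reason == rule).sum()) for rule in FILTER_RULES}
    out = table.loc[keep].reset_index(drop=True)
    report = FilterReport(
        input_rows=len(table),
        removed=removed,
        retained=int(keep.sum()),
        missing_cells_before=int(intens.isna().to_numpy().sum()),
        missing_cells_after=int(out[samples].isna().to_numpy().sum()),
    )
    if report.retained == 0:
        warnings.warn("all peptides were removed by the QC filters")
    return out, report


def log2_transform(table: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Log2-transform reporter intensities into a peptide x sample matrix.

    Missing stays missing.  A non-positive present intensity is a format
    violation and raises, naming the offending cell.
    """
    samples = list(design.sample_ids)
    mat = table.set_index("sequence")[samples].astype(float)
    bad = (mat <= 0) & mat.notna()
    if bad.to_numpy().any():
        seq = bad.index[bad.any(axis=1).to_numpy()][0]
        col = bad.columns[bad.loc[seq].to_numpy()][0]
        raise ValueError(f"non-positive intensity at peptide {seq!r}, sample {col!r}")
    return np.log2(mat)


def select_reference_sample(matrix: pd.DataFrame) -> str:
    """Pick the sample whose mean intensity is closest to the median of means.

    All-missing samples are excluded from candidacy with a warning.  Ties go
    to the earlier sample in column (design) order.
    """
    means = matrix.mean(axis=0, skipna=True)
    usable = means.dropna()
    if usable.empty:
        raise ValueError("no sample has any non-missing value")
    if len(usable) < len(means):
        warnings.warn(f"excluded all-missing samples from reference candidacy: "
                      f"{sorted(set(means.index) - set(usable.index))}")
    target = float(np.median(usable.to_numpy()))
    dist = (usable - target).abs()
    # idxmin on a Series returns the first minimum in column order
    return str(dist.idxmin())


def normalize_to_reference(matrix: pd.DataFrame, reference: str,
                           trim: float = 0.05, rank_tol: float = 0.05,
                           max_iter: int = 20, min_common: int = 20,
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each sample onto the reference with a rank-invariant log2 offset.

    For every non-reference sample, over the features observed in both it
    and the reference, the algorithm iterates: (i) rank both vectors,
    (ii) discard the ``trim`` fraction at each intensity extreme and keep
    features whose relative rank disagreement is at most ``rank_tol``,
    (iii) take the one-step biweight of the kept value differences as the
    offset, (iv) subtract it from the sample; it stops when the kept set
    stops changing (a pure shift leaves ranks unchanged, so this converges
    on the second pass) or after ``max_iter`` passes.

    Samples sharing fewer than ``min_common`` features with the reference
    fall back to a median-difference offset with a warning.

    Returns
    -------
    (normalized, offsets) :
        Normalized copy of the matrix (reference column untouched) and the
        per-sample log2 offsets that were subtracted (0 for the reference).
    """
    if reference not in matrix.columns:
        raise ValueError(f"reference sample {reference!r} not in matrix")
    out = matrix.copy()
    offsets = pd.Series(0.0, index=matrix.columns)
    ref_vals = matrix[reference]

    for sample in matrix.columns:
        if sample == reference:
            continue
        both = matrix[sample].notna() & ref_vals.notna()
        x = matrix[sample][both].to_numpy(dtype=float)
        r = ref_vals[both].to_numpy(dtype=float)
        n = x.size
        if n < min_common:
            warnings.warn(f"sample {sample!r} shares only {n} features with the "
                          f"reference; using median-difference offset")
            total = float(np.median(x - r)) if n else 0.0
        else:
            total = 0.0
            prev_kept: frozenset[int] | None = None
            for _ in range(max_iter):
                mean_int = (x + r) / 2.0
                order = np.argsort(mean_int, kind="stable")
                lo = int(np.floor(trim * n))
                trimmed = order[lo:n - lo] if n - 2 * lo >= 1 else order
                rx = rankdata(x[trimmed])
                rr = rankdata(r[trimmed])
                m = trimmed.size
                kept_idx = trimmed[np.abs(rx - rr) / m <= rank_tol]
                if kept_idx.size == 0:
                    kept_idx = trimmed
                kept = frozenset(kept_idx.tolist())
                if kept == prev_kept:
                    break
                delta = tukey_biweight(x[kept_idx] - r[kept_idx])
                x = x - delta
                total += delta
                prev_kept = kept
        out[sample] = matrix[sample] - total
        offsets[sample] = total
    # bit-identical reference column
    out[reference] = matrix[reference]
    return out, offsets
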