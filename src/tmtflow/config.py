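"""Run configuration and sample design.

A :class:`SampleDesign` ties each quantified sample to its isobaric reporter
channel (e.g. TMT 126–131) and a histology group label (e.g. ADC / SCC).
A :class:`RunConfig` collects every tunable threshold of the pipeline in one
validated, serializable object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = ["SampleDesign", "RunConfig", "read_design", "write_design"]


@dataclass(frozen=True)
class SampleDesign:
    """Mapping of samples to reporter channels and comparison groups.

    Parameters
    ----------
    sample_ids :
        Unique sample identifiers, in channel order.
    channel_labels :
        Reporter channel label per sample (e.g. ``"126"`` … ``"131"``).
    groups :
        Group label per sample (e.g. ``"ADC"`` or ``"SCC"``).
    """

    sample_ids: tuple[str, ...]
    channel_labels: tuple[str, ...]
    groups: tuple[str, ...]

    def __init__(self, sample_ids: Sequence[str], channel_labels: Sequence[str],
                 groups: Sequence[str]):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in sample_ids))
        object.__setattr__(self, "channel_labels", tuple(str(c) for c in channel_labels))
        object.__setattr__(self, "groups", tuple(str(g) for g in groups))
        self._validate()

    def _validate(self) -> None:
        n = len(self.sample_ids)
        if n == 0:
            raise ValueError("design must contain at least one sample")
        if len(self.channel_labels) != n or len(self.groups) != n:
            raise ValueError("sample_ids, channel_labels and groups must be parallel")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")

    @property
    def group_levels(self) -> tuple[str, ...]:
        """Group labels in order of first appearance."""
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == group]

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in self.group_levels}

    def require_two_groups(self) -> tuple[str, str]:
        """Return the two group levels, erroring unless exactly two exist.

        Differential analysis contrasts exactly two histologies; any other
        design is rejected here rather than deep inside a t-test loop.
        """
        levels = self.group_levels
        if len(levels) != 2:
            raise ValueError(
                f"differential analysis needs exactly two groups, got {levels!r}")
        if any(len(self.samples_in(g)) < 1 for g in levels):
            raise ValueError("each group needs at least one sample")
        return levels[0], levels[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "channel": self.channel_labels,
            "group": self.groups,
        })


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample-design TSV with columns sample_id, channel, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "channel", "group"):
        if col not in df.columns:
            raise ValueError(f"design file {path} is missing column {col!r}")
    return SampleDesign(df["sample_id"], df["channel"], df["group"])


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """All pipeline thresholds, with the published defaults.

    Attributes
    ----------
    pep_threshold :
        Posterior error probability cutoff; peptides with PEP strictly above
        this are removed (default 0.1).
    max_missing :
        Maximum tolerated missing reporter intensities per peptide row; rows
        with strictly more are removed.  ``None`` derives the threshold from
        the design as the larger of the two group sizes.
    p_threshold :
        Significance level for all tests (default 0.05, unadjusted).
    fc_linear_threshold :
        Linear fold-change cutoff for differential calls; a feature must have
        linear FC > 1.5 or < 1/1.5 (default 1.5).
    corr_r_threshold :
        Correlation cutoff for calling a gene–protein pair concordant
        (default 0.5).
    sd_probe_threshold :
        Log2-scale standard-deviation cutoff for the variable-probe filter
        (default 1.0, strict >).
    normalization :
        ``"rank_order_scale"`` for the iterative rank-invariant per-sample
        scaling, or ``"none"``.
    """

    pep_threshold: float = 0.1
    max_missing: int | None = None
    p_threshold: float = 0.05
    fc_linear_threshold: float = 1.5
    corr_r_threshold: float = 0.5
    sd_probe_threshold: float = 1.0
    seed: int = 0
    normalization: str = "rank_order_scale"
    use_fc_filter: bool = True

    def validate(self) -> "RunConfig":
        if not (0 < self.pep_threshold <= 1):
            raise ValueError("pep_threshold must be in (0, 1]")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.fc_linear_threshold <= 0:
            raise ValueError("fc_linear_threshold must be > 0")
        if self.corr_r_threshold <= 0:
            raise ValueError("corr_r_threshold must be > 0")
        if self.sd_probe_threshold <= 0:
            raise ValueError("sd_probe_threshold must be > 0")
        if self.max_missing is not None and self.max_missing < 0:
            raise ValueError("max_missing must be >= 0")
        if self.normalization not in ("rank_order_scale", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()
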