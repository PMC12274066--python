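"""Overall and recent transposable-element content from read annotations.

Low-coverage read sampling gives an assembly-free estimate of repeat
content: the fraction of sampled base pairs annotated as repetitive,
scaled to the (C-value-corrected) genome size.  "Recent" content restricts
to annotations strictly below 5% divergence from their family consensus, a
proxy for recent transposition activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PipelineConfig, logger

TE_CLASSES = ("DNA", "RC", "LTR", "LINE", "SINE", "Other", "Unknown")

_REQUIRED = ("read_id", "read_bp", "annotated_bp", "repeat_class",
             "divergence")


@dataclass
class TEContentSummary:
    """Genome-scaled repeat content for one species."""

    species: str
    te_bp: float
    recent_te_bp: float
    te_fraction: float
    recent_fraction: float
    per_class_bp: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.recent_te_bp > self.te_bp * (1 + 1e-9):
            raise ValueError("recent_te_bp exceeds te_bp")
        for frac in (self.te_fraction, self.recent_fraction):
            if not (0.0 <= frac <= 1.0 + 1e-9):
                raise ValueError("fractions must lie in [0, 1]")


def _check_annotations(annotations: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in annotations.columns]
    if missing:
        raise KeyError(f"annotation table missing columns {missing}")
    bad = annotations["annotated_bp"] > annotations["read_bp"]
    if bad.any():
        raise ValueError("annotated_bp exceeds read_bp")


def summarize_te_content(annotations: pd.DataFrame, genome_size: float,
                         species: str = "",
                         cfg: PipelineConfig | None = None,
                         ) -> TEContentSummary:
    """Overall, recent and per-class TE content scaled to genome size.

    te_fraction = sum(annotated_bp) / sum(read_bp); te_bp = te_fraction *
    genome_size; recent restricts to divergence strictly below
    ``recent_divergence_max``.  Partially annotated reads contribute their
    annotated base pairs only.
    """
    cfg = cfg or PipelineConfig()
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if annotations.empty:
        logger.warning("summarize_te_content %s: empty annotation table",
                       species)
        return TEContentSummary(species, 0.0, 0.0, 0.0, 0.0,
                                {c: 0.0 for c in TE_CLASSES})
    _check_annotations(annotations)
    sampled = float(annotations["read_bp"].sum())
    if sampled <= 0:
        raise ValueError("total sampled bp must be positive")
    annotated = float(annotations["annotated_bp"].sum())
    te_fraction = annotated / sampled
    te_bp = te_fraction * genome_size
    recent = annotations[
        annotations["divergence"] < cfg.recent_divergence_max]
    recent_bp = float(recent["annotated_bp"].sum()) / sampled * genome_size
    per_class = {}
    for cls in TE_CLASSES:
        cls_bp = float(annotations.loc[annotations["repeat_class"] == cls,
                                       "annotated_bp"].sum())
        per_class[cls] = cls_bp / sampled * genome_size
    return TEContentSummary(species=species, te_bp=te_bp,
                            recent_te_bp=recent_bp, te_fraction=te_fraction,
                            recent_fraction=recent_bp / genome_size,
                            per_class_bp=per_class)


def recent_te_content(annotations: pd.DataFrame, genome_size: float,
                      cfg: PipelineConfig | None = None) -> float:
    """Genome-scaled TE bp with divergence strictly below the recent
    threshold (a read at exactly the threshold is excluded)."""
    return summarize_te_content(annotations, genome_size,
                                cfg=cfg).recent_te_bp


def landscape_histogram(annotations: pd.DataFrame,
                        bin_width: float = 0.01) -> pd.DataFrame:
    """Annotated bp per divergence bin (half-open [lo, hi)); the basis of
    repeat-landscape plots.  Total mass equals total annotated bp."""
    if not (0 < bin_width <= 0.5):
        raise ValueError("bin_width must be in (0, 0.5]")
    _check_annotations(annotations)
    ann = annotations.dropna(subset=["divergence"])
    ann = ann[ann["annotated_bp"] > 0]
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    idx = np.minimum(np.floor(ann["divergence"].to_numpy() / bin_width),
                     len(edges) - 2).astype(int)
    mass = np.zeros(len(edges) - 1)
    np.add.at(mass, idx, ann["annotated_bp"].to_numpy(dtype=float))
    return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                         "annotated_bp": mass})


def summarize_all_species(annotations: dict[str, pd.DataFrame],
                          genome_sizes: pd.Series,
                          cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-species TE content table from per-species annotation tables."""
    rows = []
    for sp, ann in annotations.items():
        summary = summarize_te_content(ann, float(genome_sizes[sp]),
                                       species=sp, cfg=cfg)
        rows.append({"species": sp, "te_bp": summary.te_bp,
                     "recent_te_bp": summary.recent_te_bp,
                     "te_fraction": summary.te_fraction,
                     "recent_fraction": summary.recent_fraction})
    return pd.DataFrame(rows).set_index("species")
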