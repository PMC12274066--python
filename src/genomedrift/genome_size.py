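"""Genome-size estimation from C-values and assembly sizes.

Assemblies underestimate genome size, increasingly so for large genomes, so
measured C-values (flow cytometry / Feulgen densitometry) are preferred
where available.  For species without a record, the expected C-value is
predicted from a weighted least-squares regression of C-value (bp) on
assembly size (bp), trained on the species that have both.  Weights default
to 1/assembly_size^2, i.e. a multiplicative error model consistent with the
scatter growing with size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr

from .core import SpeciesTraitTable, logger

WEIGHT_SCHEMES = ("inv_size_sq", "equal")


@dataclass
class CValueModel:
    """Fitted WLS line cvalue_bp = intercept + slope * assembly_size."""

    intercept: float
    slope: float
    weighting: str
    n_records: int
    weighted_rss: float

    def __post_init__(self) -> None:
        if self.n_records < 3:
            raise ValueError("need at least 3 records")
        if not np.isfinite(self.slope):
            raise ValueError("non-finite slope")


def dedup_cvalues(records: pd.DataFrame) -> pd.DataFrame:
    """One C-value per species: keep the most recent record; average when
    dates tie.

    ``records`` needs columns species, cvalue, cvalue_date (any other
    columns of the winning rows are carried through; on a date tie the
    first row's metadata is kept with the averaged value).
    """
    for col in ("species", "cvalue", "cvalue_date"):
        if col not in records.columns:
            raise KeyError(f"dedup_cvalues requires column {col!r}")
    out = []
    for species, grp in records.groupby("species", sort=False):
        latest = grp[grp["cvalue_date"] == grp["cvalue_date"].max()]
        row = latest.iloc[0].copy()
        row["cvalue"] = latest["cvalue"].mean()
        out.append(row)
    return pd.DataFrame(out).reset_index(drop=True)


def fit_cvalue_wls(assembly_size: np.ndarray, cvalue_bp: np.ndarray,
                   weighting: str = "inv_size_sq") -> CValueModel:
    """Closed-form weighted least squares of C-value (bp) on assembly size.

    ``weighting='inv_size_sq'`` uses weights 1/assembly_size^2
    (multiplicative error); ``'equal'`` reduces to OLS.
    """
    x = np.asarray(assembly_size, dtype=float)
    y = np.asarray(cvalue_bp, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired records")
    if np.ptp(x) == 0:
        raise ValueError("singular design: all assembly sizes equal")
    if weighting not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = 1.0 / x**2 if weighting == "inv_size_sq" else np.ones_like(x)
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    fitted = res.params[0] + res.params[1] * x
    wrss = float(np.sum(w * (y - fitted) ** 2))
    return CValueModel(intercept=float(res.params[0]),
                       slope=float(res.params[1]),
                       weighting=weighting, n_records=len(x),
                       weighted_rss=wrss)


def predict_cvalue(model: CValueModel, assembly_size: float) -> float:
    """Predicted C-value in bp, floored at the assembly size (an assembly
    is a lower bound on the genome)."""
    if assembly_size <= 0:
        raise ValueError("assembly size must be positive")
    return max(model.intercept + model.slope * assembly_size,
               float(assembly_size))


def choose_genome_size(assembly_size: float, cvalue_pg: float | None,
                       model: CValueModel | None,
                       pg_to_bp: float = 0.978e9) -> tuple[float, str]:
    """The analysis' choice rule: measured C-value when present, otherwise
    the WLS-predicted C-value.  Returns (genome_size_bp, source)."""
    if cvalue_pg is not None and np.isfinite(cvalue_pg):
        return float(cvalue_pg) * pg_to_bp, "cvalue"
    if model is None:
        raise ValueError("no C-value and no fitted model")
    return predict_cvalue(model, assembly_size), "predicted"


def estimate_genome_sizes(table: SpeciesTraitTable,
                          cvalue_records: pd.DataFrame | None = None,
                          weighting: str = "inv_size_sq",
                          pg_to_bp: float = 0.978e9) -> SpeciesTraitTable:
    """Fill the ``genome_size`` column for every species in ``table``.

    The WLS is trained on deduplicated C-value records (bp) against the
    corresponding assembly sizes; species with a C-value use it directly,
    the rest get the prediction.  Adds ``genome_size`` and
    ``genome_size_source`` columns.
    """
    df = table.df.copy()
    if cvalue_records is None:
        recs = df.loc[df["cvalue"].notna(),
                      ["assembly_size", "cvalue"]].reset_index()
        recs["cvalue_date"] = 0
    else:
        recs = cvalue_records.copy()
    recs = dedup_cvalues(recs)
    model = None
    if len(recs) >= 3:
        train = recs.dropna(subset=["cvalue"])
        sizes = train["species"].map(df["assembly_size"]) \
            if "assembly_size" not in train.columns else train["assembly_size"]
        model = fit_cvalue_wls(sizes.to_numpy(),
                               train["cvalue"].to_numpy() * pg_to_bp,
                               weighting=weighting)
    else:
        logger.warning("estimate_genome_sizes: <3 C-value records, "
                       "no WLS model fitted")
    sizes, sources = [], []
    for sp, row in df.iterrows():
        cv = row.get("cvalue")
        cv = cv if cv is not None and np.isfinite(cv) else None
        gs, src = choose_genome_size(row["assembly_size"], cv, model,
                                     pg_to_bp=pg_to_bp)
        sizes.append(gs)
        sources.append(src)
    df["genome_size"] = sizes
    df["genome_size_source"] = sources
    return SpeciesTraitTable(df)


def assembly_cvalue_correlation(assembly_size: np.ndarray,
                                cvalue_bp: np.ndarray) -> dict[str, float]:
    """Pearson correlation between assembly size and C-value, on raw and on
    log values (both reported; they can differ)."""
    x = np.asarray(assembly_size, dtype=float)
    y = np.asarray(cvalue_bp, dtype=float)
    r_raw, p_raw = pearsonr(x, y)
    r_log, p_log = pearsonr(np.log(x), np.log(y))
    return {"pearson_r_raw": float(r_raw), "p_raw": float(p_raw),
            "pearson_r_log": float(r_log), "p_log": float(p_log)}
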