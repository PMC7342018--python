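"""Fixed-tissue statistics of mitotic nuclear position.

Distances of mitotic (PH3+) nuclei to the apical surface, per disc and
condition: normalization by the disc's nuclear-region height, the
fraction of nuclei deeper than a cutoff, empirical-CDF comparison with
the two-sample Kolmogorov--Smirnov test (pooling age-matched discs of a
condition before comparing), and classification of mosaic-clone
neighborhoods by the fraction of apical perimeter adjoining
RNAi-expressing cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MitoticPositionSet",
    "CloneNeighborhood",
    "TailFractionResult",
    "ECDFResult",
    "normalize_position",
    "tail_fraction",
    "ecdf",
    "ecdf_compare",
    "compare_conditions",
    "classify_clone",
]

_REQUIRED = ("disc_id", "condition", "distance_um")


@dataclass
class MitoticPositionSet:
    """Per-nucleus distances to the apical surface.

    ``data`` columns: ``disc_id``, ``condition``, ``distance_um`` and
    optionally ``region_height_um`` (the disc's nuclear-region height,
    needed for normalization).  Distances are non-negative micrometres.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"position table missing columns: {missing}")
        d = self.data["distance_um"]
        if len(d) and (not np.all(np.isfinite(d)) or (d < 0).any()):
            raise ValueError("distances must be finite and >= 0")
        if len(self.data) and self.data["disc_id"].isna().any():
            raise ValueError("every record needs a disc_id")

    def __len__(self) -> int:
        return len(self.data)

    def pooled(self, condition: str | None = None) -> np.ndarray:
        """All distances of one condition (or all), pooled across discs."""
        df = self.data
        if condition is not None:
            df = df[df["condition"] == condition]
        return df["distance_um"].to_numpy(dtype=float)


@dataclass(frozen=True)
class CloneNeighborhood:
    """A tracked mitotic cell in a mosaic clone experiment.

    ``rnai_neighbor_fraction`` is the fraction of the cell's apical
    perimeter adjoining RNAi-expressing (marker-positive) cells.
    """

    cell_genotype: str           # "wt" | "rnai"
    rnai_neighbor_fraction: float

    def __post_init__(self) -> None:
        if self.cell_genotype not in ("wt", "rnai"):
            raise ValueError(
                f"cell_genotype must be 'wt' or 'rnai', "
                f"got {self.cell_genotype!r}"
            )
        f = self.rnai_neighbor_fraction
        if not np.isfinite(f) or not 0.0 <= f <= 1.0:
            raise ValueError(
                f"rnai_neighbor_fraction must lie in [0, 1], got {f!r}"
            )


def normalize_position(pset: MitoticPositionSet) -> pd.DataFrame:
    """Divide each distance by its own disc's nuclear-region height.

    Returns a copy of the table with a dimensionless ``normalized``
    column; values above 1 (nuclei deeper than the nuclear region) are
    kept and flagged in ``beyond_region``.
    """
    df = pset.data
    if len(df) == 0:
        raise ValueError("cannot normalize an empty position set")
    if "region_height_um" not in df.columns:
        raise ValueError(
            "normalization requires a region_height_um column"
        )
    heights = df["region_height_um"]
    bad = df.loc[~np.isfinite(heights) | (heights <= 0), "disc_id"].unique()
    if bad.size:
        raise ValueError(
            "missing or non-positive nuclear-region height for discs: "
            f"{sorted(map(str, bad))}"
        )
    out = df.copy()
    out["normalized"] = out["distance_um"] / heights
    out["beyond_region"] = out["normalized"] > 1.0
    return out


@dataclass(frozen=True)
class TailFractionResult:
    """Per-disc percentages of nuclei deeper than the cutoff."""

    per_disc: pd.DataFrame   # disc_id, n, pct_beyond
    cutoff_um: float
    mean_pct: float
    sd_pct: float


def tail_fraction(
    pset: MitoticPositionSet, cutoff_um: float = 5.0
) -> TailFractionResult:
    """Percentage of mitotic nuclei strictly more than ``cutoff_um``
    from the apical surface, per disc, with a mean +/- SD summary.

    Strictly greater-than: a nucleus at exactly the cutoff counts as
    apical.
    """
    if cutoff_um <= 0:
        raise ValueError("cutoff_um must be positive")
    if len(pset) == 0:
        raise ValueError("cannot summarize an empty position set")
    rows = []
    for disc, grp in pset.data.groupby("disc_id", sort=True):
        n = len(grp)
        pct = 100.0 * float((grp["distance_um"] > cutoff_um).sum()) / n
        rows.append({"disc_id": disc, "n": n, "pct_beyond": pct})
    per_disc = pd.DataFrame(rows)
    pcts = per_disc["pct_beyond"].to_numpy()
    return TailFractionResult(
        per_disc=per_disc,
        cutoff_um=float(cutoff_um),
        mean_pct=float(pcts.mean()),
        sd_pct=float(pcts.std(ddof=1)) if pcts.size > 1 else 0.0,
    )


def ecdf(sample: np.ndarray) -> pd.DataFrame:
    """Right-continuous empirical CDF: F(x) = #{X <= x} / n at each
    distinct sample value (ties merged)."""
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size == 0:
        raise ValueError("empty sample")
    ux, counts = np.unique(x, return_counts=True)
    return pd.DataFrame({"x": ux, "F": np.cumsum(counts) / x.size})


@dataclass(frozen=True)
class ECDFResult:
    ecdf_a: pd.DataFrame
    ecdf_b: pd.DataFrame
    statistic: float    # KS D = sup |F_a - F_b|
    pvalue: float
    n_a: int
    n_b: int


def ecdf_compare(
    a: np.ndarray, b: np.ndarray, *, method: str = "asymp"
) -> ECDFResult:
    """Two-sample Kolmogorov--Smirnov comparison of distance ECDFs.

    ``method`` is passed to :func:`scipy.stats.ks_2samp`: ``"asymp"``
    (default), ``"exact"`` for small samples, or ``"auto"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method=method)
    return ECDFResult(
        ecdf_a=ecdf(a),
        ecdf_b=ecdf(b),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def compare_conditions(
    pset: MitoticPositionSet,
    condition_a: str,
    condition_b: str,
    *,
    method: str = "asymp",
) -> ECDFResult:
    """KS-compare two conditions, pooling each condition's discs first."""
    a = pset.pooled(condition_a)
    b = pset.pooled(condition_b)
    if a.size == 0:
        raise ValueError(f"no records for condition {condition_a!r}")
    if b.size == 0:
        raise ValueError(f"no records for condition {condition_b!r}")
    return ecdf_compare(a, b, method=method)


def classify_clone(neighborhood: CloneNeighborhood) -> str:
    """Assign a clone-neighborhood class from genotype and apical
    perimeter composition.

    * ``wt:wt`` — wild-type cell entirely surrounded by wild type
      (RNAi fraction 0).
    * ``wt:rnai`` — wild-type cell with 50--100% of its apical
      perimeter adjoining RNAi cells.
    * ``rnai:wt`` — RNAi cell with 50--100% wild-type perimeter
      (RNAi-neighbor fraction in [0, 0.5]).
    * ``rnai:rnai`` — RNAi cell entirely surrounded by RNAi cells.
    * ``unclassified`` — anything outside those bands (excluded from
      cohorts, but counted).

    Exactly 50% adjoining is assigned to the adjoining band.
    """
    f = neighborhood.rnai_neighbor_fraction
    if neighborhood.cell_genotype == "wt":
        if f == 0.0:
            return "wt:wt"
        if f >= 0.5:
            return "wt:rnai"
        return "unclassified"
    if f == 1.0:
        return "rnai:rnai"
    if f <= 0.5:
        return "rnai:wt"
    return "unclassified"
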