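"""Germplasm-level trait derivation, correlation and clustering.

Fourteen traits summarise each plant's season: final organ sizes (LA, PCW,
CA, FCD), growth-rate maxima (MLA_GR, MCA_GR), the curd expansion statistics
(AER, ECEP), phenology (TGP, TCA, Tmax_LA_GR, D_LA_RGP) and two
dimensionless coordination indices — GR, the growth rhythm (curd appearance
time over time of maximum leaf growth rate) and PCC, plant-curd
coordination (final curd area over final leaf area, a source-sink
allocation index).  Plants average into germplasm means (replicates are
biological replicates, so germplasm is the unit of inference); germplasms
are then compared by Pearson correlation and by Ward/Euclidean hierarchical
clustering on z-scored traits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import linregress, pearsonr

from .kinetics import CurdKinetics, KineticsSummary
from .models import goodness_of_fit
from .series import GrowthSeries

__all__ = [
    "TRAIT_COLUMNS",
    "derive_plant_traits",
    "aggregate_germplasm",
    "correlation_matrix",
    "cluster_germplasms",
    "validate_against_manual",
    "ClusterResult",
]

TRAIT_COLUMNS = (
    "LA", "PCW", "MLA_GR", "CA", "FCD", "MCA_GR", "AER",
    "ECEP", "TGP", "TCA", "D_LA_RGP", "Tmax_LA_GR", "GR", "PCC",
)


def _equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the given area (cm)."""
    return 2.0 * math.sqrt(area / math.pi)


def derive_plant_traits(
    leaf_series: GrowthSeries,
    curd_series: GrowthSeries | None,
    leaf_kinetics: KineticsSummary | None,
    curd_stats: CurdKinetics | None,
    tca: float | None,
    pcw_final: float | None = None,
    fcd_final: float | None = None,
    aer_mode: str = "expansion",
) -> dict:
    """The per-plant trait record.

    Final sizes are the last observed values.  TGP (total growth period) is
    the plant's last acquisition day; ECEP = TGP - TCA.  AER defaults to
    the mean expansion rate over the effective period,
    ``(CA_final - CA_at_appearance) / ECEP`` (``aer_mode="final"`` uses
    ``CA_final / ECEP`` instead).  Missing curd data leaves the
    curd-dependent traits as NaN with ``complete=False``.

    When no bounding-box-derived canopy width / curd diameter is supplied,
    the equivalent-circle diameter of the corresponding final area is used.
    """
    la = leaf_series.final_value
    harvest = leaf_series.final_day
    rec: dict = {
        "plant_id": leaf_series.plant_id,
        "LA": la,
        "PCW": pcw_final if pcw_final is not None else _equivalent_diameter(la),
        "TGP": harvest,
        "complete": True,
    }
    if leaf_kinetics is not None:
        rec["MLA_GR"] = leaf_kinetics.max_rate
        rec["Tmax_LA_GR"] = leaf_kinetics.t_max_rate
        rec["D_LA_RGP"] = leaf_kinetics.rapid_duration
    else:
        rec.update(MLA_GR=np.nan, Tmax_LA_GR=np.nan, D_LA_RGP=np.nan)
        rec["complete"] = False

    has_curd = curd_series is not None and len(curd_series) > 0 and tca is not None
    if has_curd:
        ca = curd_series.final_value
        ecep = harvest - tca
        if ecep <= 0:
            raise ValueError("curd appearance must precede harvest")
        ca_at_tca = float(curd_series.values[0])
        rec["CA"] = ca
        rec["FCD"] = fcd_final if fcd_final is not None else _equivalent_diameter(ca)
        rec["TCA"] = float(tca)
        rec["ECEP"] = float(ecep)
        rec["AER"] = (ca - ca_at_tca) / ecep if aer_mode == "expansion" else ca / ecep
        rec["PCC"] = ca / la
        rec["MCA_GR"] = curd_stats.max_rate if curd_stats is not None else np.nan
        tmax = rec.get("Tmax_LA_GR", np.nan)
        rec["GR"] = float(tca) / tmax if np.isfinite(tmax) and tmax > 0 else np.nan
        if curd_stats is None:
            rec["complete"] = False
    else:
        rec.update({k: np.nan for k in ("CA", "FCD", "TCA", "ECEP", "AER",
                                        "PCC", "MCA_GR", "GR")})
        rec["complete"] = False
    return rec


def aggregate_germplasm(plant_records: pd.DataFrame) -> pd.DataFrame:
    """Average plant trait records into germplasm means.

    Requires a ``germplasm_id`` column; plants flagged incomplete (e.g. no
    curd ever detected) are dropped first, and germplasms left without any
    complete plant are excluded with a warning rather than imputed.
    Returns one row per germplasm with the 14 traits plus ``n``.
    """
    df = plant_records.copy()
    if "germplasm_id" not in df.columns:
        raise ValueError("plant records need a germplasm_id column")
    all_ids = set(df["germplasm_id"])
    if "complete" in df.columns:
        df = df[df["complete"].astype(bool)]
    if df.empty:
        raise ValueError("no complete plant records to aggregate")
    dropped = all_ids - set(df["germplasm_id"])
    if dropped:
        warnings.warn(
            f"excluding germplasms with no complete plants: {sorted(dropped)}",
            stacklevel=2,
        )
    cols = [c for c in TRAIT_COLUMNS if c in df.columns]
    grouped = df.groupby("germplasm_id")[cols].mean()
    grouped["n"] = df.groupby("germplasm_id").size()
    return grouped.reset_index()


def correlation_matrix(table: pd.DataFrame, traits=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p-values across germplasms.

    Constant trait columns get NaN (undefined correlation) against every
    partner.  No multiple-testing correction is applied; p-values follow
    the conventional per-pair t-test.
    """
    traits = list(traits) if traits is not None else [
        c for c in TRAIT_COLUMNS if c in table.columns
    ]
    if len(table) < 3:
        raise ValueError("need at least 3 germplasms for correlation")
    data = table[traits].to_numpy(float)
    p_count = len(traits)
    r = np.eye(p_count)
    p = np.zeros((p_count, p_count))
    const = data.std(axis=0) == 0
    for i in range(p_count):
        for j in range(i + 1, p_count):
            if const[i] or const[j]:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = pearsonr(data[:, i], data[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    for i in range(p_count):
        if const[i]:
            r[i, i] = np.nan
            p[i, i] = np.nan
    rdf = pd.DataFrame(r, index=traits, columns=traits)
    pdf = pd.DataFrame(p, index=traits, columns=traits)
    return rdf, pdf


@dataclass(frozen=True)
class ClusterResult:
    """Ward linkage tree, cut labels, and the z-score matrix used."""

    linkage: np.ndarray
    labels: pd.Series  # germplasm_id -> group (1..k)
    zscores: pd.DataFrame
    k: int


def zscore_table(table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Column-wise z-scores (sample sd, ddof=1) of the trait table."""
    traits = list(traits) if traits is not None else [
        c for c in TRAIT_COLUMNS if c in table.columns
    ]
    sub = table[traits].astype(float)
    sd = sub.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant trait columns cannot be z-scored: {bad}")
    return (sub - sub.mean()) / sd


def cluster_germplasms(
    table: pd.DataFrame,
    k: int = 4,
    traits=None,
    id_column: str = "germplasm_id",
) -> ClusterResult:
    """Ward's minimum-variance clustering on z-scored Euclidean distances.

    The tree is cut at ``k`` groups; labels are 1..k in linkage order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} germplasms")
    z = zscore_table(table, traits)
    tree = linkage(z.to_numpy(), method="ward", metric="euclidean")
    flat = fcluster(tree, t=k, criterion="maxclust")
    ids = table[id_column] if id_column in table.columns else pd.RangeIndex(len(table))
    labels = pd.Series(flat, index=pd.Index(ids, name=id_column), name="group")
    z.index = labels.index
    return ClusterResult(linkage=tree, labels=labels, zscores=z, k=k)


def validate_against_manual(predicted, measured) -> dict[str, float]:
    """Regress image-derived trait values on manual ground truth.

    Returns the OLS slope/intercept of predicted on measured plus R², RMSE
    and MAE of the predictions against the measurements (single regressor,
    k = 1).
    """
    pred = np.asarray(predicted, float)
    meas = np.asarray(measured, float)
    if pred.shape != meas.shape:
        raise ValueError("predicted and measured must have equal length")
    if pred.size < 3:
        raise ValueError("need at least 3 paired values")
    res = linregress(meas, pred)
    gof = goodness_of_fit(meas, pred, k=1)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": gof.r2,
        "rmse": gof.rmse,
        "mae": gof.mae,
        "n": int(pred.size),
    }
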