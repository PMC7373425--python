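"""Per-cluster predictive features, contacts, outcomes and acinus summaries.

For every cluster of transduced (oncogene-expressing) cells nine features
are computed from the start-of-imaging centroids:

  f1  n_cells_acinus              cells in the acinus
  f2  density_acinus              f1 / (pi * Dmax^2), the acinus treated as a
                                  sphere with diameter Dmax = the distance
                                  between its two most distant cells
  f3  n_transduced_acinus         transduced cells in the acinus
  f4  n_cells_in_cluster_volume   all cells inside the cluster sphere (the
                                  ball centred at the cluster centroid with
                                  diameter = distance between its two
                                  farthest transduced members)
  f5  n_transduced_in_cluster     cluster members
  f6  mean_pairwise_dist_volume   mean pairwise distance, all cells in volume
  f7  mean_pairwise_dist_transduced  mean pairwise distance, cluster members
  f8  fraction_transduced_in_volume  transduced cells in volume / f4
  f9  n_contacts_transduced       member pairs closer than the contact
                                  threshold (mean cell diameter + 2 SD)

Ball membership uses a closed ball (<=); contacts use a strict inequality
("less than" the threshold).  Note the cluster sphere is defined through
its centroid, so members of a spread-out cluster can themselves fall
outside the volume (e.g. an equilateral triangle with side D has its
vertices at D/sqrt(3) > D/2 from the centroid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import ranksums
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DegenerateGeometryError
from .cluster_id import Cluster
from .io_tables import CohortTable

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "n_cells_acinus",
    "density_acinus",
    "n_transduced_acinus",
    "n_cells_in_cluster_volume",
    "n_transduced_in_cluster",
    "mean_pairwise_dist_volume",
    "mean_pairwise_dist_transduced",
    "fraction_transduced_in_volume",
    "n_contacts_transduced",
)

DEFAULT_DIAMETER_MEAN = 10.0  # µm, used when no diameter column exists
DEFAULT_DIAMETER_SD = 1.0


@dataclass(frozen=True)
class ContactRule:
    """Two cells are in contact if their centres are strictly closer than
    mean_diameter + 2 * sd_diameter."""

    mean_diameter: float
    sd_diameter: float

    @property
    def threshold(self) -> float:
        return self.mean_diameter + 2.0 * self.sd_diameter

    @classmethod
    def from_cells(
        cls,
        cells: pd.DataFrame,
        default_mean: float = DEFAULT_DIAMETER_MEAN,
        default_sd: float = DEFAULT_DIAMETER_SD,
    ) -> "ContactRule":
        """Estimate the rule from the acinus diameter column when present,
        otherwise fall back to configured defaults."""
        if "diameter" in cells.columns and cells["diameter"].notna().any():
            d = cells["diameter"].dropna().to_numpy(dtype=float)
            sd = float(d.std(ddof=1)) if len(d) > 1 else default_sd
            return cls(float(d.mean()), sd)
        return cls(default_mean, default_sd)


def acinus_geometry(cells: pd.DataFrame) -> tuple[int, float, float, float]:
    """Whole-acinus geometry: (n_cells, Dmax, sphere surface area, density).

    The acinus is treated as a sphere whose diameter Dmax is the distance
    between its two most distant cells; surface area = pi * Dmax^2 and
    density = n_cells / surface_area (cells/µm²).  Fewer than two cells, or
    all-coincident cells, make the geometry degenerate.
    """
    coords = cells[["x", "y", "z"]].to_numpy(dtype=float)
    n = len(coords)
    if n < 2:
        raise DegenerateGeometryError(f"acinus has {n} cell(s); Dmax undefined")
    dmax = float(pdist(coords).max())
    if dmax <= 0.0:
        raise DegenerateGeometryError("all cells coincident; Dmax = 0")
    surface = np.pi * dmax**2
    return n, dmax, surface, n / surface


def cluster_volume_membership(cluster: Cluster, cells: pd.DataFrame) -> set[str]:
    """Ids of all cells within the cluster sphere (closed ball).

    A singleton cluster has a radius-0 ball containing its member plus any
    exactly coincident cell.
    """
    if not cluster.members:
        raise DataError("cluster has no members")
    coords = cells[["x", "y", "z"]].to_numpy(dtype=float)
    dist = np.linalg.norm(coords - cluster.center_of_mass, axis=1)
    inside = dist <= cluster.sphere_diameter / 2.0 + 1e-12
    members = set(cells.loc[inside, "cell_id"].astype(str))
    if cluster.sphere_diameter == 0.0:
        members |= set(cluster.members)  # radius-0 ball: the member itself
    return members


def contact_count(cluster: Cluster, cells: pd.DataFrame, rule: ContactRule) -> int:
    """Unordered member pairs with centre distance strictly below threshold."""
    sub = cells[cells["cell_id"].isin(cluster.members)]
    coords = sub[["x", "y", "z"]].to_numpy(dtype=float)
    if len(coords) < 2:
        return 0
    return int((pdist(coords) < rule.threshold).sum())


def _mean_pairwise(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 0.0
    return float(pdist(coords).mean())


def compute_features(
    cells: pd.DataFrame,
    clusters: list[Cluster],
    rule: ContactRule | None = None,
) -> pd.DataFrame:
    """One feature row per cluster of one acinus.

    Singleton conventions: f4 = 1 (plus coincident cells), f5 = 1,
    f6 = f7 = 0, f8 = 1 when only the member occupies the volume, f9 = 0.
    """
    if rule is None:
        rule = ContactRule.from_cells(cells)
    n_cells, dmax, _, density = acinus_geometry(cells)
    n_transduced = int(cells["transduced"].astype(bool).sum())
    transduced_ids = set(cells.loc[cells["transduced"].astype(bool), "cell_id"].astype(str))
    rows = []
    for cluster in clusters:
        volume_ids = cluster_volume_membership(cluster, cells)
        vol = cells[cells["cell_id"].isin(volume_ids)]
        members = cells[cells["cell_id"].isin(cluster.members)]
        n_vol = len(vol)
        n_tr_vol = len(volume_ids & transduced_ids)
        rows.append(
            {
                "acinus_id": cluster.acinus_id,
                "cluster_id": cluster.cluster_id,
                "n_cells_acinus": n_cells,
                "density_acinus": density,
                "n_transduced_acinus": n_transduced,
                "n_cells_in_cluster_volume": n_vol,
                "n_transduced_in_cluster": len(cluster.members),
                "mean_pairwise_dist_volume": _mean_pairwise(
                    vol[["x", "y", "z"]].to_numpy(dtype=float)
                ),
                "mean_pairwise_dist_transduced": _mean_pairwise(
                    members[["x", "y", "z"]].to_numpy(dtype=float)
                ),
                "fraction_transduced_in_volume": n_tr_vol / n_vol if n_vol else 0.0,
                "n_contacts_transduced": contact_count(cluster, cells, rule),
                "outcome": cluster.tumor,
            }
        )
    cols = ["acinus_id", "cluster_id", *FEATURE_NAMES, "outcome"]
    return pd.DataFrame(rows, columns=cols)


def compute_features_cohort(
    cohort: CohortTable,
    clusters: dict[str, list[Cluster]],
    rule: ContactRule | None = None,
    default_diameter_mean: float = DEFAULT_DIAMETER_MEAN,
    default_diameter_sd: float = DEFAULT_DIAMETER_SD,
) -> pd.DataFrame:
    """Feature rows for every cluster of every acinus in a cohort.

    When ``rule`` is None the contact threshold is estimated per acinus
    from its diameter column (falling back to the configured defaults).
    Acini with degenerate geometry are excluded with a log entry.
    """
    frames = []
    for acinus_id in cohort.acinus_ids:
        if not clusters.get(acinus_id):
            continue
        cells = cohort.acinus(acinus_id)
        acinus_rule = rule or ContactRule.from_cells(
            cells, default_diameter_mean, default_diameter_sd
        )
        try:
            frames.append(compute_features(cells, clusters[acinus_id], acinus_rule))
        except DegenerateGeometryError as exc:
            logger.warning("acinus %s excluded: %s", acinus_id, exc)
    if not frames:
        return pd.DataFrame(columns=["acinus_id", "cluster_id", *FEATURE_NAMES, "outcome"])
    return pd.concat(frames, ignore_index=True)


def annotate_outcomes(
    clusters: dict[str, list[Cluster]],
    annotations: pd.DataFrame | None = None,
    lineage: pd.DataFrame | None = None,
    fold_expansion_threshold: float = 4.0,
) -> dict[str, list[Cluster]]:
    """Set each cluster's tumor flag.

    Explicit mode (``annotations``: acinus_id, cluster_id, tumor): outcomes
    are copied; every cluster must be covered.  Derivation mode
    (``lineage``: acinus_id, cell_id, n_start, n_end): a cluster is tumor
    if any member's lineage expanded by at least ``fold_expansion_threshold``
    over the observation window.  The threshold is a configurable heuristic
    for the phenotypic call, not a measured constant.
    """
    if (annotations is None) == (lineage is None):
        raise DataError("provide exactly one of annotations or lineage")
    if annotations is not None:
        key = {
            (str(r.acinus_id), str(r.cluster_id)): bool(r.tumor)
            for r in annotations.itertuples(index=False)
        }
        missing = [
            (c.acinus_id, c.cluster_id)
            for acinus in clusters.values()
            for c in acinus
            if (c.acinus_id, c.cluster_id) not in key
        ]
        if missing:
            raise DataError(f"clusters without outcome annotation: {missing[:10]}")
        for acinus in clusters.values():
            for c in acinus:
                c.tumor = key[(c.acinus_id, c.cluster_id)]
        return clusters
    lin = lineage.copy()
    if "n_start" not in lin.columns:
        lin["n_start"] = 1
    lin["fold"] = lin["n_end"].astype(float) / lin["n_start"].astype(float)
    fold = {
        (str(r.acinus_id), str(r.cell_id)): float(r.fold)
        for r in lin.itertuples(index=False)
    }
    for acinus in clusters.values():
        for c in acinus:
            folds = [fold.get((c.acinus_id, m), 1.0) for m in c.members]
            c.tumor = bool(max(folds) >= fold_expansion_threshold)
    return clusters


SUMMARY_FEATURES = (
    "n_cells_start",
    "n_cells_end",
    "n_transduced_start",
    "n_transduced_end",
    "density_start",
    "density_end",
    "proliferation_rate_transduced",
    "proliferation_rate_normal",
)


def acinus_summaries(
    start: CohortTable,
    end: CohortTable,
    clusters: dict[str, list[Cluster]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-acinus start/end summaries and tumor vs non-tumor comparisons.

    Proliferation rate per population is (N_end - N_start) / N_start, left
    missing when N_start = 0.  An acinus is has_tumor if any of its
    clusters is tumor-associated.  Each summary feature is compared between
    tumor and non-tumor acini with a two-sided Wilcoxon rank-sum test;
    unadjusted p-values are reported alongside a Benjamini-Hochberg column.
    """
    rows = []
    for acinus_id in start.acinus_ids:
        if acinus_id not in set(end.acinus_ids):
            continue
        s, e = start.acinus(acinus_id), end.acinus(acinus_id)
        n_s, n_e = len(s), len(e)
        tr_s = int(s["transduced"].astype(bool).sum())
        tr_e = int(e["transduced"].astype(bool).sum())
        norm_s, norm_e = n_s - tr_s, n_e - tr_e
        try:
            density_s = acinus_geometry(s)[3]
        except DegenerateGeometryError:
            density_s = np.nan
        try:
            density_e = acinus_geometry(e)[3]
        except DegenerateGeometryError:
            density_e = np.nan
        rows.append(
            {
                "acinus_id": acinus_id,
                "n_cells_start": n_s,
                "n_cells_end": n_e,
                "n_transduced_start": tr_s,
                "n_transduced_end": tr_e,
                "density_start": density_s,
                "density_end": density_e,
                "proliferation_rate_transduced": (tr_e - tr_s) / tr_s if tr_s else np.nan,
                "proliferation_rate_normal": (norm_e - norm_s) / norm_s if norm_s else np.nan,
                "has_tumor": any(
                    c.tumor for c in clusters.get(acinus_id, []) if c.tumor is not None
                ),
            }
        )
    summary = pd.DataFrame(rows)
    comparisons = []
    if len(summary) and summary["has_tumor"].nunique() == 2:
        tumor = summary[summary["has_tumor"]]
        rest = summary[~summary["has_tumor"]]
        for feat in SUMMARY_FEATURES:
            a = tumor[feat].dropna().to_numpy(dtype=float)
            b = rest[feat].dropna().to_numpy(dtype=float)
            if len(a) == 0 or len(b) == 0:
                continue
            stat, p = ranksums(a, b)
            comparisons.append(
                {
                    "feature": feat,
                    "median_tumor": float(np.median(a)),
                    "median_no_tumor": float(np.median(b)),
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    comparison = pd.DataFrame(
        comparisons,
        columns=["feature", "median_tumor", "median_no_tumor", "statistic", "p_value"],
    )
    if len(comparison):
        comparison["p_bh"] = multipletests(comparison["p_value"], method="fdr_bh")[1]
    else:
        comparison["p_bh"] = pd.Series(dtype=float)
    return summary, comparison
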