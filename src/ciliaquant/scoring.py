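"""Aggregation, significance screening and mean-rank performance scoring.

Per-object and per-image measurements are averaged to one value per slide and
parameter, then across donors.  Parameters are screened for association with
storage condition (Kruskal-Wallis across conditions on per-slide values,
p < 0.001 by default).  Finally, for each parameter the entities under
comparison (storage conditions, or antibodies) are ranked 1..n in the
parameter's "better" direction, and the per-parameter ranks are averaged into
a single overall performance rank per entity — the integrated metric used to
order storage conditions and antibodies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical scored parameters and the direction in which smaller/larger
#: values indicate more cilia-specific staining.  Specific tufts are small,
#: regular (low radial-variance compactness), stretched (high eccentricity),
#: with symmetric intensity (low mass displacement), strong red->green rank
#: agreement (high RWC) and red centroids on the marker (low distance).
DEFAULT_DIRECTIONS: dict[str, str] = {
    "AreaShape_Area": "lower",
    "AreaShape_Compactness": "lower",
    "AreaShape_Eccentricity": "higher",
    "Intensity_MassDisplacement": "lower",
    "Correlation_RWC_RED_GREEN": "higher",
    "Distance_Centroid_mCilia": "lower",
}

#: Long-format slide table columns.
SLIDE_TABLE_COLUMNS = ("donor", "condition", "antibody", "parameter", "value")


@dataclass
class RankMatrix:
    """Per-parameter integer (or midrank) ranks of entities, 1 = best."""

    ranks: pd.DataFrame                  # index: parameter, columns: entities
    axis: str = "condition"
    values: pd.DataFrame | None = None   # the entity means the ranks came from

    @property
    def entities(self) -> list[str]:
        return list(self.ranks.columns)

    def overall(self) -> pd.Series:
        return overall_performance(self.ranks)


def aggregate(
    features: pd.DataFrame,
    pairs: pd.DataFrame,
    coloc: pd.DataFrame,
    unique_only: bool = True,
) -> pd.DataFrame:
    """Collapse measurement tables to one value per (slide, parameter).

    features : per-object table with donor/condition/antibody/image_id/
        object_id/channel plus AreaShape_* and Intensity_* columns; only
        test-channel objects are scored.
    pairs : per-pair table with red_id/green_multiplicity/distance_um.
    coloc : per-image table with Correlation_RWC_RED_GREEN.

    With ``unique_only`` (the default), object and distance parameters are
    restricted to red objects whose green parent has exactly one red child,
    so both channels' measurements describe the same cilium.  Slides where no
    object survives contribute no rows (missing data, reported via logging).
    """
    key = ["donor", "condition", "antibody"]
    rows: list[pd.DataFrame] = []

    feat = features[features["channel"] == "test"].copy()
    if unique_only and not pairs.empty:
        unique = pairs[(pairs["green_multiplicity"] == 1) & pairs["green_id"].notna()]
        feat = feat.merge(
            unique[key + ["image_id", "red_id"]].rename(columns={"red_id": "object_id"}),
            on=key + ["image_id", "object_id"],
            how="inner",
        )
    param_cols = {
        "AreaShape_Area": "AreaShape_Area",
        "AreaShape_Compactness": "AreaShape_Compactness",
        "AreaShape_Eccentricity": "AreaShape_Eccentricity",
        "Intensity_MassDisplacement": "Intensity_MassDisplacement",
    }
    if not feat.empty:
        melted = feat.melt(
            id_vars=key, value_vars=list(param_cols), var_name="parameter",
            value_name="value",
        )
        rows.append(melted.groupby(key + ["parameter"], as_index=False)["value"].mean())

    if not pairs.empty:
        dist = pairs[pairs["green_id"].notna()]
        if unique_only:
            dist = dist[dist["green_multiplicity"] == 1]
        if not dist.empty:
            d = dist.groupby(key, as_index=False)["distance_um"].mean()
            d["parameter"] = "Distance_Centroid_mCilia"
            rows.append(d.rename(columns={"distance_um": "value"}))

    if not coloc.empty:
        c = coloc.groupby(key, as_index=False)["Correlation_RWC_RED_GREEN"].mean()
        c["parameter"] = "Correlation_RWC_RED_GREEN"
        rows.append(c.rename(columns={"Correlation_RWC_RED_GREEN": "value"}))

    if not rows:
        return pd.DataFrame(columns=list(SLIDE_TABLE_COLUMNS))
    table = pd.concat(rows, ignore_index=True)[list(SLIDE_TABLE_COLUMNS)]
    table = table.dropna(subset=["value"]).reset_index(drop=True)
    n_expected = features[key].drop_duplicates().shape[0]
    n_got = table[key].drop_duplicates().shape[0]
    if n_got < n_expected:
        logger.warning("%d slide(s) contributed no surviving measurements",
                       n_expected - n_got)
    return table


def condition_antibody_means(slide_table: pd.DataFrame) -> pd.DataFrame:
    """Mean across donors for every (condition, antibody, parameter)."""
    return (slide_table
            .groupby(["condition", "antibody", "parameter"], as_index=False)["value"]
            .mean())


def screen_parameters(
    slide_table: pd.DataFrame,
    alpha: float = 0.001,
    method: str = "kruskal",
    fdr: bool = False,
) -> tuple[set[str], dict[str, float]]:
    """Screen parameters for association with storage condition.

    Per parameter, per-slide values are grouped by condition and compared
    with a Kruskal-Wallis test (``method="anova"`` for one-way ANOVA).
    Parameters with p < alpha are flagged significant.  ``fdr`` applies a
    Benjamini-Hochberg adjustment before the alpha cut (off by default).
    Parameters with fewer than two conditions holding two observations each
    are skipped with a warning.
    """
    if method not in ("kruskal", "anova"):
        raise ValueError(f"unknown screen method {method!r}")
    pvals: dict[str, float] = {}
    for parameter, sub in slide_table.groupby("parameter"):
        groups = [g["value"].to_numpy() for _, g in sub.groupby("condition")]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            logger.warning("parameter %s: fewer than 2 usable condition groups, "
                           "skipped", parameter)
            continue
        if np.ptp(np.concatenate(groups)) == 0:
            # identical values everywhere: trivially not significant
            pvals[parameter] = 1.0
            continue
        try:
            if method == "kruskal":
                stat = stats.kruskal(*groups)
            else:
                stat = stats.f_oneway(*groups)
            pvals[parameter] = float(stat.pvalue)
        except ValueError as exc:   # e.g. all values identical
            logger.warning("parameter %s: test undefined (%s)", parameter, exc)
            pvals[parameter] = 1.0
    if fdr and pvals:
        names = sorted(pvals)
        adj = _benjamini_hochberg(np.array([pvals[n] for n in names]))
        pvals = dict(zip(names, adj.tolist()))
    significant = {p for p, v in pvals.items() if v < alpha}
    return significant, pvals


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return adj


def rank_entities(
    table: pd.DataFrame,
    direction: Mapping[str, str] | None = None,
    axis: str = "condition",
    condition_subset: Sequence[str] | None = None,
    parameters: Iterable[str] | None = None,
) -> RankMatrix:
    """Rank conditions or antibodies per parameter, 1 = best.

    For each parameter, entity values are the means of ``table``'s per-slide
    (or per-condition-antibody) values over everything except the chosen
    axis; entities are then ranked in the parameter's better direction
    (midranks on ties, logged).  ``condition_subset`` restricts which
    conditions contribute before ranking — used for the "all conditions
    except prolonged room temperature" antibody comparison.
    """
    if axis not in ("condition", "antibody"):
        raise ValueError(f"axis must be 'condition' or 'antibody', got {axis!r}")
    direction = dict(direction or DEFAULT_DIRECTIONS)
    sub = table
    if condition_subset is not None:
        sub = sub[sub["condition"].isin(list(condition_subset))]
    if parameters is not None:
        sub = sub[sub["parameter"].isin(list(parameters))]
    if sub.empty:
        raise ValueError("no rows left to rank")

    missing = sorted(set(sub["parameter"]) - set(direction))
    if missing:
        raise ValueError(f"no better-direction defined for parameter(s): {missing}")

    values = sub.pivot_table(index="parameter", columns=axis, values="value",
                             aggfunc="mean")
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"entities with missing parameter means: {bad}")

    ranks = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    for parameter, row in values.iterrows():
        v = row.to_numpy(dtype=float)
        if direction[parameter] == "higher":
            v = -v
        r = stats.rankdata(v, method="average")
        if np.unique(v).size < v.size:
            logger.info("parameter %s: tied entity values, midranks used", parameter)
        ranks.loc[parameter] = r
    return RankMatrix(ranks=ranks, axis=axis, values=values)


def overall_performance(ranks: RankMatrix | pd.DataFrame) -> pd.Series:
    """Mean of the per-parameter ranks for every entity, best first.

    Accepts a :class:`RankMatrix` or a plain parameters x entities rank
    frame.  Values are rounded to 1 decimal for reporting, mirroring how the
    integrated metric is conventionally printed.
    """
    frame = ranks.ranks if isinstance(ranks, RankMatrix) else ranks
    overall = frame.mean(axis=0).round(1)
    return overall.sort_values(kind="stable")


def performance_report(
    slide_table: pd.DataFrame,
    out_dir: str | Path,
    direction: Mapping[str, str] | None = None,
    alpha: float = 0.001,
    condition_subset: Sequence[str] | None = None,
    plots: bool = False,
) -> dict[str, Path]:
    """Write heatmap-ready CSVs and rank tables for one scored study.

    Emits one antibody x condition mean-value CSV per parameter (rows and
    columns ordered best-to-worst in the parameter's direction), the
    condition and antibody overall-rank tables (plus a subset variant when
    ``condition_subset`` is given), and a JSON sidecar with screen p-values
    and sample counts.  Deterministic: identical inputs give byte-identical
    outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    direction = dict(direction or DEFAULT_DIRECTIONS)
    paths: dict[str, Path] = {}

    means = condition_antibody_means(slide_table)
    for parameter, sub in means.groupby("parameter"):
        pivot = sub.pivot_table(index="antibody", columns="condition",
                                values="value", aggfunc="mean")
        ascending = direction.get(parameter, "lower") == "lower"
        pivot = pivot.loc[
            pivot.mean(axis=1).sort_values(ascending=ascending, kind="stable").index,
            pivot.mean(axis=0).sort_values(ascending=ascending, kind="stable").index,
        ]
        p = out_dir / f"parameter__{parameter}.csv"
        pivot.to_csv(p, float_format="%.15g")
        paths[f"parameter__{parameter}"] = p
        if plots:
            _heatmap(pivot, parameter, p.with_suffix(".png"))

    for axis in ("condition", "antibody"):
        if slide_table[axis].nunique() < 2:
            logger.warning("only one %s present: %s ranking skipped", axis, axis)
            continue
        rm = rank_entities(slide_table, direction, axis=axis)
        out = rm.ranks.copy()
        out.loc["Overall_Performance_Rank"] = rm.ranks.mean(axis=0).round(1)
        out = out[rm.overall().index]
        p = out_dir / f"ranks__{axis}.csv"
        out.to_csv(p, float_format="%.15g")
        paths[f"ranks__{axis}"] = p

    if condition_subset is not None and slide_table["antibody"].nunique() >= 2:
        rm = rank_entities(slide_table, direction, axis="antibody",
                           condition_subset=condition_subset)
        out = rm.ranks.copy()
        out.loc["Overall_Performance_Rank"] = rm.ranks.mean(axis=0).round(1)
        out = out[rm.overall().index]
        p = out_dir / "ranks__antibody_subset.csv"
        out.to_csv(p, float_format="%.15g")
        paths["ranks__antibody_subset"] = p

    significant, pvals = screen_parameters(slide_table, alpha=alpha)
    sidecar = {
        "alpha": alpha,
        "significant": sorted(significant),
        "p_values": {k: pvals[k] for k in sorted(pvals)},
        "n_slides": int(slide_table[["donor", "condition", "antibody"]]
                        .drop_duplicates().shape[0]),
        "n_values": int(len(slide_table)),
        "condition_subset": list(condition_subset) if condition_subset else None,
    }
    p = out_dir / "screen.json"
    with open(p, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    paths["screen"] = p
    return paths


def _heatmap(pivot: pd.DataFrame, title: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
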