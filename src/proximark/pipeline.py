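"""Experiment orchestration: cohorts -> marker tables -> classification grid.

Mirrors the study protocol: for each (contrast, marker, grouping, adjustment,
timepoint-mode) cell, run the leave-one-of-each-class-out PLS+LDA pipeline on
the corresponding marker table and report the out-of-fold AUC and rank-sum
p-value.  Contrasts are pairwise over NC/MCI/AD, plus the converter contrast
(MCI-c vs MCI-nc) which uses MCI subjects only, by default on the longitudinal
delta features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import learn, regionstats
from .phantom import AtrophySpec, CohortNoise, PhantomSpec, iter_cohort
from .regionstats import (
    META_COLUMNS,
    FractionDefs,
    GroupingDef,
    delta_table,
    feature_columns,
    features_for_volume,
    marker_table,
)

__all__ = [
    "ExperimentCell",
    "ExperimentResult",
    "ADJUSTMENTS",
    "simulate_marker_tables",
    "extract_tables",
    "run_cell",
    "run_grid",
    "default_grid",
    "render_report",
]

logger = logging.getLogger(__name__)

ADJUSTMENTS = ("none", "age_sex", "wb_bl", "hp_bl")
CONVERTER_CLASSES = ("MCI-nc", "MCI-c")


@dataclass(frozen=True)
class ExperimentCell:
    """One cell of the experiment grid."""

    contrast: tuple[str, str]
    marker: str                    # surface | landmarks | hp_fraction | wb_fraction
    grouping: str | None = None
    adjustment: str = "none"
    timepoint_mode: str = "bl"     # bl | delta

    def label(self) -> str:
        g = f"/{self.grouping}" if self.grouping else ""
        return f"{self.contrast[0]}-{self.contrast[1]} {self.marker}{g} [{self.timepoint_mode}, {self.adjustment}]"


@dataclass
class ExperimentResult:
    cell: ExperimentCell
    auc: float
    p_value: float
    statistic: float
    n_neg: int
    n_pos: int
    scores: pd.DataFrame  # id, class, score
    cv: learn.CVResult


# ---------------------------------------------------------------------------
# marker-table production
# ---------------------------------------------------------------------------


def simulate_marker_tables(
    spec: PhantomSpec,
    atrophy: AtrophySpec,
    n_per_class: Mapping[str, int],
    seed: int,
    *,
    grouping: GroupingDef,
    fraction_defs: FractionDefs | None = None,
    kinds: Sequence[str] = ("surface",),
    timepoints: Sequence[str] = ("bl",),
    n_converters: int = 0,
    noise: CohortNoise = CohortNoise(),
    include_delta: bool = False,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Generate a phantom cohort in memory and extract marker tables.

    Returns ``{(kind, timepoint): table}``; with ``include_delta`` the
    longitudinal difference tables appear under timepoint ``"delta"``.
    Volumes are discarded as soon as their features are computed, so cohort
    size is not memory-bound.
    """
    if include_delta and not {"bl", "m12"} <= set(timepoints):
        raise ValueError("delta tables need both 'bl' and 'm12' timepoints")
    records: dict[tuple[str, str], list[dict]] = {(k, tp): [] for k in kinds for tp in timepoints}
    names_cache: dict[str, list[str]] = {}
    for record, vols in iter_cohort(
        spec, atrophy, n_per_class, seed,
        n_converters=n_converters, noise=noise, timepoints=timepoints,
    ):
        meta = {
            "id": record.id, "diagnosis": record.diagnosis, "converter": record.converter,
            "age_bl": record.age_bl, "sex": record.sex,
        }
        for tp, vol in vols.items():
            for kind in kinds:
                values, names = features_for_volume(vol, kind, grouping, fraction_defs)
                names_cache[kind] = names
                records[(kind, tp)].append({**meta, "timepoint": tp, **dict(zip(names, values))})
    tables = {}
    for (kind, tp), recs in records.items():
        t = pd.DataFrame(recs)[META_COLUMNS + names_cache[kind]]
        t.attrs["kind"] = kind
        tables[(kind, tp)] = t
    if include_delta:
        for kind in kinds:
            tables[(kind, "delta")] = delta_table(tables[(kind, "bl")], tables[(kind, "m12")], kind)
    return tables


def extract_tables(
    manifest: pd.DataFrame,
    label_names: Mapping[int, str],
    *,
    grouping: GroupingDef,
    fraction_defs: FractionDefs | None = None,
    kinds: Sequence[str] = ("surface",),
    timepoints: Sequence[str] = ("bl",),
    include_delta: bool = False,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Extract marker tables from an on-disk cohort (manifest with paths)."""
    if include_delta and not {"bl", "m12"} <= set(timepoints):
        raise ValueError("delta tables need both 'bl' and 'm12' timepoints")
    tables = {}
    for kind in kinds:
        for tp in timepoints:
            tables[(kind, tp)] = marker_table(
                manifest, kind, grouping, tp,
                fraction_defs=fraction_defs, label_names=label_names,
            )
        if include_delta:
            tables[(kind, "delta")] = delta_table(tables[(kind, "bl")], tables[(kind, "m12")], kind)
    return tables


def class_volume_summary(tables: dict[tuple[str, str], pd.DataFrame]) -> pd.DataFrame | None:
    """Per-class mean (sd) of the volume-fraction markers, if present."""
    frames = []
    for (kind, tp), t in tables.items():
        if kind in regionstats.VOLUME_KINDS:
            col = feature_columns(t)[0]
            g = t.groupby("diagnosis")[col].agg(["mean", "std"])
            g.insert(0, "timepoint", tp)
            g.insert(0, "marker", kind)
            frames.append(g.reset_index())
    return pd.concat(frames, ignore_index=True) if frames else None


# ---------------------------------------------------------------------------
# running cells
# ---------------------------------------------------------------------------


def _class_labels(table: pd.DataFrame, contrast: tuple[str, str]) -> np.ndarray:
    if set(contrast) <= set(CONVERTER_CLASSES):
        is_mci = table["diagnosis"].to_numpy() == "MCI"
        conv = table["converter"].to_numpy().astype(bool)
        out = np.where(is_mci & conv, "MCI-c", np.where(is_mci, "MCI-nc", "other"))
        return out
    return table["diagnosis"].to_numpy()


def _covariates(
    table: pd.DataFrame,
    adjustment: str,
    volume_bl: pd.DataFrame | None,
) -> np.ndarray | None:
    if adjustment == "none":
        return None
    if adjustment == "age_sex":
        sex01 = (table["sex"].to_numpy() == "F").astype(float)
        return np.column_stack([table["age_bl"].to_numpy(dtype=float), sex01])
    if adjustment in ("wb_bl", "hp_bl"):
        if volume_bl is None:
            raise ValueError(f"adjustment {adjustment!r} needs baseline volume-fraction tables")
        col = "wb_fraction" if adjustment == "wb_bl" else "hp_fraction"
        lookup = volume_bl.set_index("id")[col]
        return lookup.loc[table["id"]].to_numpy(dtype=float).reshape(-1, 1)
    raise ValueError(f"unknown adjustment {adjustment!r}; expected one of {ADJUSTMENTS}")


def run_cell(
    cell: ExperimentCell,
    tables: dict[tuple[str, str], pd.DataFrame],
    *,
    grouping: GroupingDef | None = None,
    volume_bl: pd.DataFrame | None = None,
    n_components: int = 10,
    gate_alpha: float = 0.05,
    seed: int = 0,
) -> ExperimentResult:
    """Run one grid cell: CV pipeline, AUC and rank-sum on out-of-fold scores."""
    key = (cell.marker, cell.timepoint_mode)
    if key not in tables:
        raise KeyError(f"no marker table for {key}")
    table = tables[key]
    X = table[feature_columns(table)].to_numpy(dtype=float)
    labels = _class_labels(table, cell.contrast)
    covariates = _covariates(table, cell.adjustment, volume_bl)
    landmark_regions = None
    if cell.marker == "landmarks":
        if grouping is None:
            raise ValueError("landmark cells need the grouping for per-fold alignment")
        landmark_regions = grouping.region_names
    config = learn.PipelineConfig(
        n_components=n_components, gate_alpha=gate_alpha, landmark_regions=landmark_regions,
    )
    cv = learn.cv_leave_one_per_class(
        X, labels, cell.contrast, covariates=covariates, config=config, seed=seed,
    )
    stat, p = cv.ranksum()
    scores = pd.DataFrame({
        "id": table["id"].to_numpy()[cv.indices],
        "class": labels[cv.indices],
        "score": cv.scores,
    })
    return ExperimentResult(
        cell=cell, auc=cv.auc, p_value=p, statistic=stat,
        n_neg=int((cv.y < 0).sum()), n_pos=int((cv.y > 0).sum()),
        scores=scores, cv=cv,
    )


def run_grid(
    cells: Iterable[ExperimentCell],
    tables: dict[tuple[str, str], pd.DataFrame],
    *,
    grouping: GroupingDef | None = None,
    volume_bl: pd.DataFrame | None = None,
    n_components: int = 10,
    gate_alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Run every cell; cells that cannot run are reported as skipped rows.

    Each requested cell appears exactly once in the output, either with its
    AUC/p-value or with a skip reason in ``status``.
    """
    rows = []
    for cell in cells:
        base = {
            "contrast": f"{cell.contrast[0]}-{cell.contrast[1]}",
            "marker": cell.marker,
            "grouping": cell.grouping or "",
            "adjustment": cell.adjustment,
            "timepoint_mode": cell.timepoint_mode,
        }
        try:
            res = run_cell(
                cell, tables, grouping=grouping, volume_bl=volume_bl,
                n_components=n_components, gate_alpha=gate_alpha, seed=seed,
            )
            rows.append({**base, "auc": res.auc, "p_value": res.p_value,
                         "n_neg": res.n_neg, "n_pos": res.n_pos, "status": "ok"})
        except (ValueError, KeyError) as exc:
            logger.warning("cell %s skipped: %s", cell.label(), exc)
            rows.append({**base, "auc": np.nan, "p_value": np.nan,
                         "n_neg": 0, "n_pos": 0, "status": f"skipped: {exc}"})
    return pd.DataFrame(rows)


def default_grid(
    markers: Sequence[str] = ("surface", "landmarks", "hp_fraction", "wb_fraction"),
    grouping: str = "brain",
    adjustments: Sequence[str] = ("none",),
    timepoint_modes: Sequence[str] = ("bl",),
    include_converter: bool = True,
) -> list[ExperimentCell]:
    """The study's experiment grid: all pairwise diagnosis contrasts for every
    marker/adjustment/timepoint mode, plus the converter contrast on delta
    features."""
    contrasts = [("NC", "AD"), ("NC", "MCI"), ("MCI", "AD")]
    cells = [
        ExperimentCell(contrast=c, marker=m,
                       grouping=grouping if m in ("surface", "landmarks") else None,
                       adjustment=a, timepoint_mode=tp)
        for a in adjustments
        for tp in timepoint_modes
        for m in markers
        for c in contrasts
    ]
    if include_converter:
        cells += [
            ExperimentCell(contrast=CONVERTER_CLASSES, marker=m,
                           grouping=grouping if m in ("surface", "landmarks") else None,
                           adjustment=adjustments[0], timepoint_mode="delta")
            for m in markers
        ]
    return cells


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_ADJ_TITLES = {
    "none": "not adjusted",
    "age_sex": "age and sex adjusted",
    "wb_bl": "whole-brain adjusted (baseline volume)",
    "hp_bl": "hippocampus adjusted (baseline volume)",
}


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def render_report(results: pd.DataFrame) -> str:
    """Human-readable summary grouped by adjustment mode.

    Significance flags: ``*`` p < 0.05, ``**`` p < 0.001 (uncorrected).
    """
    lines = ["Proximity-marker classification results", "=" * 42]
    if results.empty:
        lines.append("(no results)")
        return "\n".join(lines) + "\n"
    for adjustment in [a for a in ADJUSTMENTS if a in set(results["adjustment"])]:
        sub = results[results["adjustment"] == adjustment]
        lines += ["", f"-- {_ADJ_TITLES.get(adjustment, adjustment)} --"]
        header = f"{'contrast':<14}{'marker':<14}{'grouping':<10}{'mode':<8}{'AUC':>7}  {'p-value':>10}"
        lines.append(header)
        for _, r in sub.iterrows():
            if r["status"] != "ok":
                lines.append(f"{r['contrast']:<14}{r['marker']:<14}{r['grouping']:<10}"
                             f"{r['timepoint_mode']:<8}{'--':>7}  {r['status']}")
                continue
            lines.append(
                f"{r['contrast']:<14}{r['marker']:<14}{r['grouping']:<10}{r['timepoint_mode']:<8}"
                f"{r['auc']:>7.3f}  {r['p_value']:>10.3g} {_stars(r['p_value'])}"
            )
    lines += ["", "* p < 0.05, ** p < 0.001 (rank-sum on out-of-fold scores;",
              "  no multiple-comparison correction is applied)"]
    return "\n".join(lines) + "\n"
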