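"""End-to-end orchestration: cohort -> shape graphs -> measures -> statistics.

The pipeline slices each subject's state blocks to a centered window,
concatenates them, builds the Mapper shape graph, restricts to the largest
connected component when necessary (recording the discarded frame fraction),
computes the full measure row, and runs the statistical battery over the
assembled measure table joined with psychometrics.  Every random choice is
driven by seeds recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .exceptions import (
    DegenerateDataError,
    DesignError,
    ParameterError,
    StatescapeError,
    ValidationError,
)
from .mapper import ShapeGraph, mapper_graph
from .measures import (
    CROSS_SESSION_PAIRS,
    MEASURE_COLUMNS,
    compute_all_measures,
)
from .stats import (
    by_fdr,
    correlation_matrix,
    fit_mixed_lm,
    insightfulness_model,
    median_split_test,
    mixed_anova,
    paired_t,
    welch_t,
)
from .synthetic import (
    STATES,
    CohortParams,
    LabeledTimeSeries,
    PsychometricTable,
    generate_cohort,
)

logger = logging.getLogger("statescape")

__all__ = ["RunConfig", "slice_and_concatenate", "run_subject", "run_cohort"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"                      # "synthetic" | "files"
    cohort: CohortParams = field(default_factory=CohortParams)
    input_dir: str | None = None                 # files mode
    psychometrics_path: str | None = None
    filter_method: str = "linear"
    filter_seed: int = 0
    bins: int = 30
    overlap: float = 0.5
    k: int = 3
    min_neighbors: int = 3
    window: int = 100
    out_dir: str | None = None
    log_level: str = "INFO"
    write_graphs: bool = True
    distance_pairs: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ParameterError("mode must be 'synthetic' or 'files'")
        if self.window < 1:
            raise ParameterError("window must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortParams(**raw.pop("cohort", {}))
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "distance_pairs" in raw and raw["distance_pairs"] is not None:
            raw["distance_pairs"] = tuple(tuple(p) for p in raw["distance_pairs"])
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        if d["distance_pairs"] is not None:
            d["distance_pairs"] = [list(p) for p in d["distance_pairs"]]
        return d


def slice_and_concatenate(
    series: LabeledTimeSeries, window: int = 100
) -> LabeledTimeSeries:
    """Keep the centered ``window`` frames of every state block.

    Block start offset is ``floor((L - window) / 2)``; blocks are re-joined
    in their original order with labels preserved.
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    keep: list[np.ndarray] = []
    for state in _block_order(series.labels):
        idx = series.state_block(state)
        length = idx.size
        if length < window:
            raise ValidationError(
                f"state block {state!r} has {length} frames < window {window}"
            )
        start = (length - window) // 2
        keep.append(idx[start:start + window])
    sel = np.concatenate(keep)
    return LabeledTimeSeries(
        values=series.values[sel],
        labels=series.labels[sel],
        subject_id=series.subject_id,
        group=series.group,
    )


def _block_order(labels: np.ndarray) -> list[str]:
    """Distinct labels in order of first appearance (contiguous blocks)."""
    order: list[str] = []
    for lab in labels:
        if not order or order[-1] != lab:
            if lab in order:
                raise ValidationError(f"label {lab!r} blocks are not contiguous")
            order.append(str(lab))
    return order


def run_subject(
    series: LabeledTimeSeries, config: RunConfig
) -> tuple[ShapeGraph, dict, dict]:
    """Process one subject: slice -> Mapper -> measures.

    Returns the (possibly component-restricted) shape graph, the measure-table
    row and a manifest entry.  Raises with the subject id attached on any
    stage failure.
    """
    t0 = time.perf_counter()
    try:
        missing = [s for s in STATES if s not in set(map(str, series.labels))]
        if missing:
            raise ValidationError(f"missing state block(s): {', '.join(missing)}")
        sliced = slice_and_concatenate(series, window=config.window)
        sg = mapper_graph(
            sliced.values,
            labels=sliced.labels,
            filter_method=config.filter_method,
            seed=config.filter_seed,
            bins=config.bins,
            overlap=config.overlap,
            k=config.k,
            min_neighbors=config.min_neighbors,
        )
        n_components = sg.n_components()
        sg_used, discarded = sg.largest_component()
        row = compute_all_measures(
            sg_used,
            subject_id=series.subject_id,
            group=series.group,
            distance_pairs=config.distance_pairs,
        )
    except StatescapeError as exc:
        raise type(exc)(f"[{series.subject_id}] {exc}") from exc
    entry = {
        "subject_id": series.subject_id,
        "group": series.group,
        "n_nodes": sg_used.n_nodes,
        "n_edges": sg_used.n_edges,
        "n_components": n_components,
        "discarded_mass_fraction": discarded,
        "elapsed_s": round(time.perf_counter() - t0, 4),
    }
    return sg_used, row, entry


def _anova_family_frames(measures: pd.DataFrame) -> list[tuple[str, str, str, float]]:
    """(test name, session-1 column, session-2 column, correction factor)."""
    fams: list[tuple[str, str, str, float]] = []
    for m in ("dc", "cc", "diam"):
        for cond in ("FA", "OM", "RS"):
            fams.append((f"{m}_{cond}", f"{m}_{cond}1", f"{m}_{cond}2", 3.0))
    for a, b in (("FA", "OM"), ("FA", "RS"), ("OM", "RS")):
        fams.append((f"d_{a}_{b}", f"d_{a}1_{b}1", f"d_{a}2_{b}2", 1.0))
    return fams


def _long_format(measures: pd.DataFrame, col1: str, col2: str) -> pd.DataFrame:
    rows = []
    for _, r in measures.iterrows():
        for session, col in ((1, col1), (2, col2)):
            rows.append({"subject_id": r["subject_id"], "group": r["group"],
                         "session": session, "value": r[col]})
    return pd.DataFrame(rows).dropna(subset=["value"])


def run_cohort_stats(
    measures: pd.DataFrame, psychometrics: pd.DataFrame
) -> tuple[pd.DataFrame, "object", dict]:
    """Run the full statistical battery on an assembled measure table.

    Returns (stats results table, correlation result, extras dict with the
    mixed-model / median-split / insightfulness fits).  Tests that cannot run
    on the provided data are flagged in the results table, not raised.
    """
    table = measures.merge(psychometrics, on=["subject_id", "group"], how="left")
    rows: list[dict] = []

    def add(name, effect, statistic, df, df2, p, p_corr, correction, note=""):
        rows.append({
            "test": name, "effect": effect, "statistic": statistic,
            "df1": df, "df2": df2, "p_raw": p, "p_corrected": p_corr,
            "correction": correction, "note": note,
        })

    # Mixed ANOVAs per measure family; cc/dc/diam corrected x3 per condition.
    for fam, col1, col2, factor in _anova_family_frames(measures):
        try:
            long = _long_format(measures, col1, col2)
            res = mixed_anova(long, dv="value")
            for effect, tr in res.items():
                corr_name = f"x{int(factor)}" if factor > 1 else "none"
                p_corr = min(1.0, tr.p * factor)
                add(f"anova_{fam}", effect, tr.statistic, tr.df, tr.df2,
                    tr.p, p_corr, corr_name)
        except (DesignError, DegenerateDataError, ParameterError, KeyError) as exc:
            add(f"anova_{fam}", "all", np.nan, np.nan, np.nan, np.nan, np.nan,
                "none", f"not-run: {exc}")

    # Post-hoc paired t (session effect) per family, BY-corrected per block.
    posthoc: list[tuple[str, object]] = []
    for fam, col1, col2, _ in _anova_family_frames(measures):
        try:
            pairs = measures.dropna(subset=[col1, col2])
            tr = paired_t(pairs[col1], pairs[col2], name=f"paired_t_{fam}")
            posthoc.append((fam, tr))
        except (ParameterError, DegenerateDataError, KeyError) as exc:
            add(f"paired_t_{fam}", "session", np.nan, np.nan, np.nan, np.nan,
                np.nan, "none", f"not-run: {exc}")
    if posthoc:
        adj = by_fdr([tr.p for _, tr in posthoc])
        for (fam, tr), p_corr in zip(posthoc, adj):
            add(f"paired_t_{fam}", "session", tr.statistic, tr.df, np.nan,
                tr.p, float(p_corr), "benjamini-yekutieli")

    # Group (Welch) t tests on the cross-session distances, BY-corrected.
    cross: list[tuple[str, object]] = []
    for a, b in CROSS_SESSION_PAIRS:
        col = f"d_{a}_{b}"
        try:
            x = table.loc[table["group"] == "control", col]
            y = table.loc[table["group"] == "active", col]
            cross.append((col, welch_t(x, y, name=f"welch_t_{col}")))
        except (ParameterError, DegenerateDataError, KeyError) as exc:
            add(f"welch_t_{col}", "group", np.nan, np.nan, np.nan, np.nan,
                np.nan, "none", f"not-run: {exc}")
    if cross:
        adj = by_fdr([tr.p for _, tr in cross])
        for (col, tr), p_corr in zip(cross, adj):
            add(f"welch_t_{col}", "group", tr.statistic, tr.df, np.nan,
                tr.p, float(p_corr), "benjamini-yekutieli")

    # Post-session group t on d(OM2, RS2) — the headline contrast.
    try:
        x = table.loc[table["group"] == "control", "d_OM2_RS2"]
        y = table.loc[table["group"] == "active", "d_OM2_RS2"]
        tr = welch_t(x, y, name="welch_t_d_OM2_RS2")
        add("welch_t_d_OM2_RS2", "group", tr.statistic, tr.df, np.nan,
            tr.p, tr.p, "none")
    except (ParameterError, DegenerateDataError, KeyError) as exc:
        add("welch_t_d_OM2_RS2", "group", np.nan, np.nan, np.nan, np.nan,
            np.nan, "none", f"not-run: {exc}")

    # Correlation battery: all measures vs psychometric scales (Kendall).
    scales = [c for c in ("positive_derealization", "insightfulness")
              if c in table.columns]
    measure_cols = [c for c in MEASURE_COLUMNS
                    if c in table.columns and table[c].notna().sum() >= 4]
    corr = None
    if scales and measure_cols:
        corr = correlation_matrix(table, measure_cols, scales, method="kendall")

    extras: dict = {}
    # Mixed LM: d(OM*, RS*) ~ derealization x session, per-subject intercept.
    try:
        long = _long_format(measures, "d_OM1_RS1", "d_OM2_RS2")
        long = long.merge(
            table[["subject_id", "positive_derealization"]].drop_duplicates(),
            on="subject_id", how="left",
        ).dropna(subset=["positive_derealization"])
        extras["mixed_lm"] = fit_mixed_lm(
            long, "value", "positive_derealization * session")
        mm = extras["mixed_lm"]
        for term in mm.params.index:
            if term == "Intercept":
                continue
            add("mixed_lm_d_OM_RS", term, float(mm.params.loc[term, "stat"]),
                np.nan, np.nan, float(mm.params.loc[term, "p"]),
                float(mm.params.loc[term, "p"]), "none",
                note=mm.note)
    except (StatescapeError, KeyError, ValueError) as exc:
        add("mixed_lm_d_OM_RS", "all", np.nan, np.nan, np.nan, np.nan,
            np.nan, "none", f"not-run: {exc}")

    # Median split of derealization: paired session test per subgroup.
    try:
        ms = median_split_test(table, "positive_derealization",
                               "d_OM1_RS1", "d_OM2_RS2")
        extras["median_split"] = ms
        for label, tr in ms.items():
            add(f"median_split_{label}", "session", tr.statistic, tr.df,
                np.nan, tr.p, tr.p, "none", note=tr.note)
    except (StatescapeError, KeyError) as exc:
        add("median_split", "all", np.nan, np.nan, np.nan, np.nan, np.nan,
            "none", f"not-run: {exc}")

    # Insightfulness ~ derealization x d(OM1, OM2).
    try:
        extras["insightfulness"] = insightfulness_model(table)
        im = extras["insightfulness"]
        add("insightfulness_model", "overall_F", im.full_f, im.full_df[0],
            im.full_df[1], im.full_f_p, im.full_f_p, "none",
            note=f"adj_r2={im.full_adj_r2:.6g};reduced_adj_r2={im.reduced_adj_r2:.6g}")
    except (StatescapeError, KeyError, ValueError) as exc:
        add("insightfulness_model", "all", np.nan, np.nan, np.nan, np.nan,
            np.nan, "none", f"not-run: {exc}")

    return pd.DataFrame(rows), corr, extras


def run_cohort(
    config: RunConfig,
    subjects: list[LabeledTimeSeries] | None = None,
    psychometrics: PsychometricTable | None = None,
) -> dict:
    """Run the full pipeline for a cohort.

    Subjects may be passed directly; otherwise they are generated
    (``synthetic`` mode) or loaded from ``input_dir`` (``files`` mode).
    Returns a dict with the measure table, stats table, correlation result,
    per-subject graphs, the manifest, and the exclusion list.  When
    ``config.out_dir`` is set, all outputs are also written to disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t_start = time.time()
    if subjects is None:
        if config.mode == "synthetic":
            subjects, psychometrics = generate_cohort(config.cohort)
        else:
            subjects, psychometrics = _load_file_cohort(config)
    if psychometrics is None:
        raise ParameterError("psychometrics table required")

    rows: list[dict] = []
    graphs: dict[str, ShapeGraph] = {}
    manifest_entries: list[dict] = []
    excluded: list[dict] = []
    for series in subjects:
        try:
            sg, row, entry = run_subject(series, config)
        except StatescapeError as exc:
            logger.warning("excluding subject %s: %s", series.subject_id, exc)
            excluded.append({"subject_id": series.subject_id, "reason": str(exc)})
            continue
        rows.append(row)
        graphs[series.subject_id] = sg
        manifest_entries.append(entry)
        logger.info("subject %s: %d nodes, %d edges (%.2fs)",
                    series.subject_id, entry["n_nodes"], entry["n_edges"],
                    entry["elapsed_s"])

    measures = pd.DataFrame(rows)
    stats_table, corr, extras = run_cohort_stats(measures, psychometrics.frame)

    manifest = {
        "config": config.to_dict(),
        "subjects": manifest_entries,
        "excluded": excluded,
        "n_input_subjects": len(subjects),
        "software_version": _version(),
        "started_at": t_start,
        "finished_at": time.time(),
    }
    result = {
        "measures": measures,
        "stats": stats_table,
        "correlations": corr,
        "extras": extras,
        "graphs": graphs,
        "manifest": manifest,
        "excluded": excluded,
        "psychometrics": psychometrics,
    }
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("statescape")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _load_file_cohort(config: RunConfig) -> tuple[list[LabeledTimeSeries], PsychometricTable]:
    if not config.input_dir:
        raise ParameterError("files mode requires input_dir")
    input_dir = Path(config.input_dir)
    matrices = sorted(input_dir.glob("*_matrix.tsv"))
    if not matrices:
        raise ParameterError(f"no *_matrix.tsv inputs found in {input_dir}")
    psy_path = Path(config.psychometrics_path or input_dir / "psychometrics.csv")
    if not psy_path.exists():
        raise ParameterError(f"psychometrics table not found: {psy_path}")
    psychometrics = sio.load_psychometrics(psy_path)
    group_of = dict(zip(psychometrics.frame["subject_id"],
                        psychometrics.frame["group"]))
    subjects = []
    for mpath in matrices:
        sid = mpath.name[: -len("_matrix.tsv")]
        lpath = input_dir / f"{sid}_labels.csv"
        if not lpath.exists():
            raise ParameterError(f"labels file missing for {sid}")
        if sid not in group_of:
            raise ParameterError(f"subject {sid} missing from psychometrics")
        subjects.append(sio.load_timeseries(mpath, lpath, sid, group_of[sid]))
    return subjects, psychometrics


def _write_outputs(result: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.12g"
    result["measures"].to_csv(out / "measures.csv", index=False,
                              float_format=float_fmt)
    result["stats"].to_csv(out / "stats.csv", index=False, float_format=float_fmt)
    corr = result["correlations"]
    if corr is not None:
        corr.r.to_csv(out / "correlations_r.csv", float_format=float_fmt)
        corr.p_corrected.to_csv(out / "correlations_p.csv", float_format=float_fmt)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result["manifest"], fh, indent=1, sort_keys=True)
    if config.write_graphs:
        gdir = out / "graphs"
        for sid, sg in result["graphs"].items():
            sio.graph_to_graphml(sg, gdir / f"{sid}.graphml")
            sio.graph_to_json(sg, gdir / f"{sid}.json")
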