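"""End-to-end cohort analysis: from a directory of recordings to a report.

For every participant x condition recording the pipeline trims the test
span, integrates the pitch angle and extracts cycle amplitudes, computes the
angular-velocity SDs, the full-span SampEn of all six channels and the
partial windowed SampEn of the configured channels.  Cohort-level results
are the per-condition summaries (mean +/- SD), paired box-vs-stool
comparisons, the per-window through-origin regressions with optimal-duration
selection, and Bland-Altman agreement between the full-test and
short-window entropies.

Reports are plain nested dictionaries, serialised as deterministic JSON
(sorted keys); every cohort summary is recomputable from the per-participant
records it aggregates, and a report round-trips through its own reader.  A
recording that fails a stage is skipped with a logged reason rather than
aborting the cohort.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .agreement import (
    bland_altman,
    compare_conditions,
    cross_condition_correlation,
    regress_through_origin,
    select_duration,
)
from .convergence import sampen_partials
from .kinematics import detect_cycles, integrate_gyro, velocity_sds
from .recording import CHANNELS, IMURecording, read_recording, segment_test
from .sampen import SampEnParams, sampen

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "CohortReport", "analyze_recording", "analyze_cohort", "run_pipeline"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable analysis parameters, with the study's defaults."""

    m: int = 2
    r_value: float = 0.2
    r_mode: str = "relative"
    r_scope: str = "window"
    min_length: int = 200
    marker_channel: str = "gyr_y"
    zero_tol: float = 2.0  # deg/s
    launch_frac: float = 0.1
    require_marker: bool = True
    detrend: bool = True
    min_prominence_frac: float = 0.2
    t_start: float = 10.0  # s, habituation phase to discard
    t_end: float = 70.0  # s, window cap
    step: float = 2.0  # s, window increment
    partial_channels: tuple[str, ...] = ("gyr_x",)
    bland_altman_I: int = 28  # window end for the agreement analysis
    r2_threshold: float = 0.99
    slope_threshold: float = 0.95

    @property
    def sampen_params(self) -> SampEnParams:
        return SampEnParams(m=self.m, r_mode=self.r_mode, r_value=self.r_value)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "partial_channels" in data:
            data = {**data, "partial_channels": tuple(data["partial_channels"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class CohortReport:
    """Structured pipeline output; a thin wrapper over a JSON-safe dict."""

    data: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.data, fh, sort_keys=True, indent=2, allow_nan=False)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "CohortReport":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(data=json.load(fh))

    @property
    def participants(self) -> list[dict]:
        return self.data["participants"]


def _jsonable(value):
    """Coerce numpy scalars/arrays and NaN to JSON-safe python values."""
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, np.ndarray):
        return [_jsonable(v) for v in value.tolist()]
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (float, np.floating)):
        value = float(value)
        return None if not math.isfinite(value) else value
    return value


def analyze_recording(rec: IMURecording, config: PipelineConfig | None = None) -> dict:
    """Single-recording analysis: trim, amplitude, SDs, SampEn50, partials."""
    if config is None:
        config = PipelineConfig()
    trimmed = segment_test(
        rec,
        marker_channel=config.marker_channel,
        zero_tol=config.zero_tol,
        launch_frac=config.launch_frac,
        require_marker=config.require_marker,
    )
    gx = trimmed["gyr_x"]
    angle = integrate_gyro(gx, detrend=config.detrend)
    cycles = detect_cycles(angle, min_prominence_frac=config.min_prominence_frac)
    sds = velocity_sds(trimmed)
    params = config.sampen_params

    sampen50_by_channel = {}
    for name in CHANNELS:
        res = sampen(trimmed[name].values, params, min_length=config.min_length)
        sampen50_by_channel[name] = {
            "sampen": res.sampen,
            "A": res.match_count_m1,
            "B": res.match_count_m,
            "n_templates": res.n_templates,
        }

    partials = {}
    for name in config.partial_channels:
        table = sampen_partials(
            trimmed[name],
            params,
            t_start=config.t_start,
            t_end=config.t_end,
            step=config.step,
            r_scope=config.r_scope,
        )
        partials[name] = {str(i): res.sampen for i, res in table.partials.items()}

    return _jsonable(
        {
            "participant": rec.meta.get("participant_id", ""),
            "condition": rec.meta.get("condition", ""),
            "n_samples": rec.n_samples,
            "start_index": gx.start_index,
            "end_index": gx.end_index,
            "duration_s": gx.duration,
            "mean_amplitude_deg": cycles.mean_amplitude,
            "n_cycles": cycles.n_cycles,
            "sd_x": sds.sd_x,
            "sd_y": sds.sd_y,
            "sd_z": sds.sd_z,
            "sampen50": sampen50_by_channel,
            "partials": partials,
        }
    )


def _condition_summary(records: list[dict]) -> dict:
    scalars = ("duration_s", "mean_amplitude_deg", "sd_x", "sd_y", "sd_z")
    out = {}
    for key in scalars:
        vals = np.array([r[key] for r in records], dtype=float)
        out[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)), "n": int(vals.size)}
    for name in CHANNELS:
        vals = np.array(
            [r["sampen50"][name]["sampen"] for r in records if r["sampen50"][name]["sampen"] is not None],
            dtype=float,
        )
        if vals.size:
            out[f"sampen50_{name}"] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
    return out


def _paired_vectors(by_participant: dict, key_fn) -> tuple[np.ndarray, np.ndarray]:
    box, stool = [], []
    for pid in sorted(by_participant):
        conds = by_participant[pid]
        if "box" in conds and "stool" in conds:
            vb = key_fn(conds["box"])
            vs = key_fn(conds["stool"])
            if vb is not None and vs is not None:
                box.append(vb)
                stool.append(vs)
    return np.asarray(box, dtype=float), np.asarray(stool, dtype=float)


def _comparisons(by_participant: dict) -> dict:
    out = {}
    specs = [
        ("duration_s", "wilcoxon"),
        ("mean_amplitude_deg", "paired_t"),
        ("sd_x", "wilcoxon"),
        ("sd_y", "wilcoxon"),
        ("sd_z", "wilcoxon"),
    ]
    for key, test in specs:
        box, stool = _paired_vectors(by_participant, lambda r, k=key: r[k])
        if box.size >= 5:
            try:
                stat, p = compare_conditions(box, stool, test=test)
                out[key] = {"test": test, "statistic": stat, "p": p, "n": int(box.size)}
            except ValueError as exc:
                out[key] = {"test": test, "error": str(exc)}
    for name in CHANNELS:
        box, stool = _paired_vectors(
            by_participant, lambda r, c=name: r["sampen50"][c]["sampen"]
        )
        if box.size >= 5:
            try:
                stat, p = compare_conditions(box, stool, test="wilcoxon")
                out[f"sampen50_{name}"] = {
                    "test": "wilcoxon", "statistic": stat, "p": p, "n": int(box.size),
                }
            except ValueError as exc:
                out[f"sampen50_{name}"] = {"test": "wilcoxon", "error": str(exc)}
        if box.size >= 3:
            r, p = cross_condition_correlation(box, stool)
            out.setdefault("cross_condition_correlation", {})[name] = {
                "pearson_r": r, "p": p, "n": int(box.size),
            }
    return out


def _convergence_analysis(records: list[dict], channel: str, config: PipelineConfig) -> dict | None:
    """Per-window regressions, duration selection and Bland-Altman for one
    channel within one condition."""
    rows = [r for r in records if channel in r.get("partials", {})]
    if len(rows) < 3:
        return None
    i_values = sorted({int(i) for r in rows for i in r["partials"][channel]})
    table = {}
    reg_table = {}
    for i in i_values:
        pairs = [
            (r["partials"][channel][str(i)], r["sampen50"][channel]["sampen"])
            for r in rows
            if r["partials"][channel].get(str(i)) is not None
            and r["sampen50"][channel]["sampen"] is not None
        ]
        if len(pairs) < 3:
            continue
        y = np.array([p[0] for p in pairs])
        x = np.array([p[1] for p in pairs])
        res = regress_through_origin(y, x)
        reg_table[i] = res
        table[str(i)] = {
            "k": res.k, "se_k": res.se_k, "r_squared": res.r_squared,
            "pearson_r": res.pearson_r, "p_value": res.p_value, "n": res.n,
        }
    if not reg_table:
        return None
    selection = select_duration(
        reg_table, r2_threshold=config.r2_threshold, slope_threshold=config.slope_threshold
    )

    ba = None
    i_ba = config.bland_altman_I
    pairs = [
        (r["partials"][channel][str(i_ba)], r["sampen50"][channel]["sampen"])
        for r in rows
        if r["partials"][channel].get(str(i_ba)) is not None
        and r["sampen50"][channel]["sampen"] is not None
    ]
    if len(pairs) >= 3:
        partial = np.array([p[0] for p in pairs])
        full = np.array([p[1] for p in pairs])
        res = bland_altman(partial, full)  # differences: partial - full
        ba = {
            "I": i_ba, "bias": res.bias, "sd_diff": res.sd_diff,
            "loa_low": res.loa_low, "loa_high": res.loa_high, "n": res.n,
            "means": res.means, "diffs": res.diffs,
        }
    return _jsonable(
        {
            "regressions": table,
            "optimal_I": selection.optimal_I,
            "r2_threshold": config.r2_threshold,
            "slope_threshold": config.slope_threshold,
            "bland_altman": ba,
        }
    )


def analyze_cohort(
    recordings: list[IMURecording],
    config: PipelineConfig | None = None,
    *,
    single_condition: bool = False,
) -> CohortReport:
    """Analyse a cohort of recordings grouped by participant and condition."""
    if config is None:
        config = PipelineConfig()

    rates = {round(rec.sampling_rate, 6) for rec in recordings}
    if len(rates) > 1:
        raise ValueError(f"mixed sampling rates in cohort: {sorted(rates)}")

    records: list[dict] = []
    skipped: list[dict] = []
    for rec in recordings:
        label = f"{rec.meta.get('participant_id', '?')}/{rec.meta.get('condition', '?')}"
        try:
            records.append(analyze_recording(rec, config))
        except (ValueError, KeyError) as exc:
            logger.warning("skipping %s: %s", label, exc)
            skipped.append({"recording": label, "reason": str(exc)})

    by_participant: dict[str, dict[str, dict]] = {}
    for r in records:
        by_participant.setdefault(r["participant"], {})[r["condition"]] = r

    required = 1 if single_condition else 2
    complete = [pid for pid, conds in by_participant.items() if len(conds) >= required]
    if len(complete) < 2:
        raise ValueError(
            f"need at least 2 participants with {'a' if single_condition else 'both'} "
            f"condition recording(s); got {len(complete)}"
        )

    conditions = sorted({r["condition"] for r in records})
    summary = {
        cond: _condition_summary([r for r in records if r["condition"] == cond])
        for cond in conditions
    }
    comparisons = _comparisons(by_participant) if not single_condition else {}

    convergence = {}
    for cond in conditions:
        cond_records = [r for r in records if r["condition"] == cond]
        for channel in config.partial_channels:
            result = _convergence_analysis(cond_records, channel, config)
            if result is not None:
                convergence[f"{channel}/{cond}"] = result

    data = {
        "schema_version": SCHEMA_VERSION,
        "config": _jsonable(asdict(config)),
        "provenance": {
            "software": "bendr",
            "version": __version__,
            "n_recordings": len(recordings),
            "seeds": sorted(
                {int(rec.meta["rng_seed"]) for rec in recordings if "rng_seed" in rec.meta}
            ),
        },
        "participants": records,
        "skipped": skipped,
        "summary": summary,
        "comparisons": comparisons,
        "convergence": convergence,
    }
    return CohortReport(data=_jsonable(data))


def run_pipeline(input_dir, config: PipelineConfig | None = None, **kwargs) -> CohortReport:
    """Read every ``*.csv`` recording under ``input_dir`` and analyse the cohort."""
    input_dir = Path(input_dir)
    files = sorted(input_dir.glob("*.csv"))
    if not files:
        raise ValueError(f"no recordings (*.csv) found in {input_dir}")
    recordings = [read_recording(f) for f in files]
    return analyze_cohort(recordings, config, **kwargs)
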