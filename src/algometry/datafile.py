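"""Session datafile (CSV) and protocol/scenario configuration I/O.

The session datafile is a single UTF-8 CSV with three delimited blocks:

* a commented **header** ("#"-prefixed lines) holding the settings snapshot
  (JSON), the ISO 8601 session timestamp, participant id, operator notes and
  per-repetition baseline forces — the "#" prefix keeps the continuous block
  loadable by generic CSV tools;
* a **continuous** block, one row per sample:
  ``repetition,t_s,force_N,evas,trigger`` with times in seconds from task
  start (6 decimals);
* a **summary** block (after a ``# === SUMMARY ===`` marker): per-repetition
  peaks, per-cycle force-time areas (AUC), trigger-instant force/eVAS rows
  and the cross-repetition means.

Configurations (gauge, acquisition, protocol, simulator models) live in a
YAML file; TOML is read via the stdlib parser.  Unknown keys are rejected
and defaults are filled in and echoed back on save.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import AcquisitionConfig, GaugeSpec
from .protocol import (
    AscendingProtocol,
    CycleSpec,
    TrainProtocol,
    validate_protocol,
)
from .session import SampleStream, SessionSummary, TestResult, TriggerEvent, summarize_session
from .simulator import OperatorModel, SubjectModel

_CONTINUOUS_MARKER = "# === CONTINUOUS ==="
_SUMMARY_MARKER = "# === SUMMARY ==="
_FORMAT_LINE = "# algometry-session v1"


# ---------------------------------------------------------------------------
# session datafile
# ---------------------------------------------------------------------------

def write_datafile(
    results: list[TestResult],
    summary: SessionSummary,
    settings: dict,
    path,
    participant_id: str = "",
    notes: str = "",
    timestamp: datetime | None = None,
) -> None:
    """Write a complete session (all repetitions) to one CSV datafile."""
    path = Path(path)
    ts = (timestamp or datetime.now(timezone.utc)).isoformat()
    lines: list[str] = [
        _FORMAT_LINE,
        f"# created: {ts}",
        f"# participant_id: {participant_id}",
        f"# notes: {notes}",
        f"# settings: {json.dumps(settings, sort_keys=True)}",
    ]
    for r in results:
        lines.append(f"# baseline_force_N[{r.repetition_index}]: {r.baseline_force!r}")
        if r.notes:
            lines.append(f"# repetition_notes[{r.repetition_index}]: {r.notes}")

    lines.append(_CONTINUOUS_MARKER)
    frames = []
    for r in results:
        s = r.stream
        frames.append(
            pd.DataFrame(
                {
                    "repetition": r.repetition_index,
                    "t_s": s.times,
                    "force_N": s.force,
                    "evas": s.evas,
                    "trigger": s.trigger.astype(int),
                }
            )
        )
    continuous = pd.concat(frames, ignore_index=True)
    lines.append("repetition,t_s,force_N,evas,trigger")
    for rep, t, f, e, tr in continuous.itertuples(index=False):
        lines.append(f"{int(rep)},{t:.6f},{f:.9g},{e:.9g},{int(tr)}")

    lines.append(_SUMMARY_MARKER)
    lines.append("section,repetition,ordinal,t_s,value_a,value_b")
    for r in results:
        lines.append(
            f"peak,{r.repetition_index},0,{r.peak_time:.6f},{r.peak_force:.9g},"
        )
        for ev in r.trigger_events:
            lines.append(
                f"trigger,{r.repetition_index},{ev.ordinal},{ev.t:.6f},"
                f"{ev.force_at_event:.9g},{ev.evas_at_event:.9g}"
            )
        for i, auc in enumerate(r.per_cycle_impulses):
            lines.append(f"cycle_auc,{r.repetition_index},{i},,{auc:.9g},")
        lines.append(
            f"limit,{r.repetition_index},0,"
            f"{'' if r.limit_first_time is None else f'{r.limit_first_time:.6f}'},"
            f"{int(r.limit_exceeded)},"
        )
    lines.append(f"mean_peak,,,,{summary.mean_peak_force:.9g},")
    if summary.mean_first_trigger_force is not None:
        lines.append(
            f"mean_first_trigger,,,,{summary.mean_first_trigger_force:.9g},"
            f"{summary.n_first_triggers}"
        )
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write session datafile to {path}: {exc}") from exc


class DatafileError(ValueError):
    """Malformed session datafile."""


def read_datafile(path) -> tuple[list[TestResult], SessionSummary, dict]:
    """Read a session datafile back into results, summary and settings.

    The summary is recomputed from the reconstructed per-repetition results
    (peaks, trigger events, per-cycle AUCs round-trip through the stored
    rows); numeric content round-trips to 1e-6.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or lines[0] != _FORMAT_LINE:
        raise DatafileError(f"{path}: line 1: not an algometry-session v1 file")
    try:
        i_cont = lines.index(_CONTINUOUS_MARKER)
    except ValueError:
        raise DatafileError(f"{path}: missing continuous block marker") from None
    try:
        i_sum = lines.index(_SUMMARY_MARKER)
    except ValueError:
        raise DatafileError(f"{path}: missing summary block marker") from None

    header: dict[str, str] = {}
    for n, line in enumerate(lines[1:i_cont], start=2):
        if not line.startswith("# ") or ": " not in line:
            raise DatafileError(f"{path}: line {n}: malformed header line {line!r}")
        key, _, value = line[2:].partition(": ")
        header[key] = value
    try:
        settings = json.loads(header.get("settings", "{}"))
    except json.JSONDecodeError as exc:
        raise DatafileError(f"{path}: settings header is not valid JSON: {exc}")

    from io import StringIO

    cont = pd.read_csv(StringIO("\n".join(lines[i_cont + 1 : i_sum])))
    summ = pd.read_csv(
        StringIO("\n".join(lines[i_sum + 1 :])),
        dtype={"section": str},
    )

    results: list[TestResult] = []
    for rep, grp in cont.groupby("repetition", sort=True):
        rep = int(rep)
        times = grp["t_s"].to_numpy()
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise DatafileError(
                f"{path}: continuous rows of repetition {rep} are not "
                "strictly time-ordered"
            )
        stream = SampleStream(
            times=times,
            force=grp["force_N"].to_numpy(),
            evas=grp["evas"].to_numpy(),
            trigger=grp["trigger"].to_numpy().astype(bool),
        )
        srows = summ[summ["repetition"] == rep]
        peak_rows = srows[srows["section"] == "peak"]
        if len(peak_rows) != 1:
            raise DatafileError(f"{path}: repetition {rep}: expected one peak row")
        events = [
            TriggerEvent(
                ordinal=int(r.ordinal),
                t=float(r.t_s),
                force_at_event=float(r.value_a),
                evas_at_event=float(r.value_b),
            )
            for r in srows[srows["section"] == "trigger"].itertuples()
        ]
        aucs = [
            float(r.value_a)
            for r in srows[srows["section"] == "cycle_auc"]
            .sort_values("ordinal")
            .itertuples()
        ]
        limit_rows = srows[srows["section"] == "limit"]
        exceeded = bool(int(limit_rows["value_a"].iloc[0])) if len(limit_rows) else False
        first_time = (
            float(limit_rows["t_s"].iloc[0])
            if len(limit_rows) and not pd.isna(limit_rows["t_s"].iloc[0])
            else None
        )
        results.append(
            TestResult(
                repetition_index=rep,
                baseline_force=float(header.get(f"baseline_force_N[{rep}]", 0.0)),
                peak_force=float(peak_rows["value_a"].iloc[0]),
                peak_time=float(peak_rows["t_s"].iloc[0]),
                trigger_events=events,
                per_cycle_impulses=aucs,
                limit_exceeded=exceeded,
                limit_first_time=first_time,
                stream=stream,
                notes=header.get(f"repetition_notes[{rep}]", ""),
            )
        )
    if not results:
        raise DatafileError(f"{path}: continuous block holds no samples")
    return results, summarize_session(results), settings


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_KNOWN_TOP = {"gauge", "acquisition", "protocol", "operator", "subject"}
_PROTOCOL_KEYS = {
    "ascending": {
        "type", "loading_rate", "safety_limit", "n_repetitions",
        "inter_test_interval",
    },
    "train": {
        "type", "f", "a", "p", "d", "r_a", "r_d", "baseline", "n_stimuli",
        "inter_stimulus_interval", "safety_limit", "n_repetitions",
        "inter_test_interval",
    },
}


class ConfigError(ValueError):
    """Invalid configuration file."""


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown keys in {section!r}: {sorted(unknown)} "
            f"(allowed: {sorted(allowed)})"
        )


def load_config(path) -> dict:
    """Load and validate a YAML/TOML configuration (by file extension).

    Returns a dict with any of the keys ``gauge`` (GaugeSpec),
    ``acquisition`` (AcquisitionConfig), ``protocol`` (Ascending or Train),
    ``operator`` (OperatorModel) and ``subject`` (SubjectModel); defaults are
    filled in for omitted fields, and unknown keys are rejected.
    """
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    elif path.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text(encoding="utf-8"))
    else:
        raise ConfigError(f"unsupported config extension {path.suffix!r}")
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys("top level", raw, _KNOWN_TOP)

    out: dict = {}
    if "acquisition" in raw:
        _check_keys("acquisition", raw["acquisition"],
                    {"sampling_frequency", "channels"})
        acq = dict(raw["acquisition"])
        if "channels" in acq:
            acq["channels"] = tuple(acq["channels"])
        out["acquisition"] = AcquisitionConfig(**acq)
    else:
        out["acquisition"] = AcquisitionConfig()
    if "gauge" in raw:
        _check_keys("gauge", raw["gauge"],
                    {"voltage_range_total", "force_range_total", "tip_contact_area"})
        out["gauge"] = GaugeSpec(**raw["gauge"])
    if "protocol" in raw:
        p = dict(raw["protocol"])
        ptype = p.get("type")
        if ptype not in _PROTOCOL_KEYS:
            raise ConfigError(
                f"protocol.type must be 'ascending' or 'train', got {ptype!r}"
            )
        _check_keys("protocol", p, _PROTOCOL_KEYS[ptype])
        p.pop("type")
        if ptype == "ascending":
            out["protocol"] = AscendingProtocol(
                **p, acquisition=out["acquisition"]
            )
        else:
            if "a" in p:
                cycle = CycleSpec(
                    f=p.pop("f"), a=p.pop("a"), p=p.pop("p"), d=p.pop("d", 0.0),
                    baseline=p.pop("baseline", 0.0),
                )
                p.pop("r_a", None)
                p.pop("r_d", None)
            else:
                from .protocol import make_cycle_fixed_rates

                cycle = make_cycle_fixed_rates(
                    f=p.pop("f"), r_a=p.pop("r_a"), p=p.pop("p"),
                    r_d=p.pop("r_d", None), baseline=p.pop("baseline", 0.0),
                )
            out["protocol"] = TrainProtocol(
                cycle=cycle, acquisition=out["acquisition"], **p
            )
        violations = validate_protocol(out["protocol"])
        if violations:
            raise ConfigError("invalid protocol: " + "; ".join(violations))
    if "operator" in raw:
        _check_keys("operator", raw["operator"],
                    {"tracking_time_constant", "noise_sd", "seed"})
        out["operator"] = OperatorModel(**raw["operator"])
    if "subject" in raw:
        _check_keys(
            "subject", raw["subject"],
            {"detection_threshold", "pain_threshold", "tolerance_threshold",
             "reaction_time", "evas_slope", "seed"},
        )
        out["subject"] = SubjectModel(**raw["subject"])
    return out


def config_to_dict(config: dict) -> dict:
    """Serializable snapshot of a loaded config, defaults filled in."""
    out: dict = {}
    if "gauge" in config:
        g = config["gauge"]
        out["gauge"] = {
            "voltage_range_total": g.voltage_range_total,
            "force_range_total": g.force_range_total,
        }
        if g.tip_contact_area is not None:
            out["gauge"]["tip_contact_area"] = g.tip_contact_area
    acq = config.get("acquisition", AcquisitionConfig())
    out["acquisition"] = {
        "sampling_frequency": acq.sampling_frequency,
        "channels": list(acq.channels),
    }
    if "protocol" in config:
        p = config["protocol"]
        if isinstance(p, AscendingProtocol):
            out["protocol"] = {
                "type": "ascending",
                "loading_rate": p.loading_rate,
                "safety_limit": p.safety_limit,
                "n_repetitions": p.n_repetitions,
                "inter_test_interval": p.inter_test_interval,
            }
        else:
            out["protocol"] = {
                "type": "train",
                "f": p.cycle.f,
                "a": p.cycle.a,
                "p": p.cycle.p,
                "d": p.cycle.d,
                "baseline": p.cycle.baseline,
                "n_stimuli": p.n_stimuli,
                "inter_stimulus_interval": p.inter_stimulus_interval,
                "safety_limit": p.safety_limit,
                "n_repetitions": p.n_repetitions,
                "inter_test_interval": p.inter_test_interval,
            }
    for key in ("operator", "subject"):
        if key in config:
            out[key] = asdict(config[key])
    return out


def save_config(config: dict, path) -> None:
    """Save a config (as returned by load_config) to YAML, defaults echoed."""
    path = Path(path)
    if path.suffix not in (".yaml", ".yml"):
        raise ConfigError(
            f"save_config writes YAML; unsupported extension {path.suffix!r}"
        )
    path.write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=True), encoding="utf-8"
    )
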