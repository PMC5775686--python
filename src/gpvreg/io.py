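"""Subject-table I/O, validation, and scenario (de)serialisation.

The on-disk subject table is a comma-delimited UTF-8 file with a header and
columns ``subject_id, time, event, waiting_time``; an empty waiting_time
field means the 0->1 transition was not observed -- deliberately conflating
"no donor exists" with "unknown because follow-up ended", since the analysis
only ever uses observed transitions plus the IPCW correction.  An optional
``donor_known_absent`` column is accepted and ignored.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig
from .simulate import PiecewiseHazard, ScenarioSpec

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "validate_subjects", "read_subjects",
           "write_subjects", "load_scenario", "save_scenario"]

_REQUIRED = ("subject_id", "time", "event", "waiting_time")


def validate_subjects(df: pd.DataFrame, t_search: float | None = None
                      ) -> pd.DataFrame:
    """Check the subject-table invariants; raise with row indices on failure."""
    df = df.copy()
    if "subject_id" not in df.columns:
        df.insert(0, "subject_id", np.arange(len(df)))
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"subject table lacks column(s) {missing}")
    if "donor_known_absent" in df.columns:
        logger.info("column 'donor_known_absent' present; it is not used by "
                    "the analysis and will be ignored")

    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy()
    w = df["waiting_time"].to_numpy(dtype=float)

    def _complain(mask, why):
        if np.any(mask):
            rows = np.nonzero(mask)[0][:20].tolist()
            raise ValueError(f"{why} (row index {rows})")

    _complain(~np.isfinite(time) | (time < 0),
              "follow-up time must be finite and >= 0")
    _complain(~np.isin(event, (0, 1)), "event indicator must be 0 or 1")
    has_w = ~np.isnan(w)
    _complain(has_w & (w <= 0), "waiting_time must be > 0 when present")
    _complain(has_w & (w > time),
              "transition after end of follow-up (waiting_time > time)")
    if t_search is not None:
        _complain(has_w & (w > t_search + 1e-12),
                  f"waiting_time exceeds the search window t_search={t_search}")
    return df


def read_subjects(path, t_search: float | None = None) -> pd.DataFrame:
    """Read and validate a subject CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    return validate_subjects(df, t_search=t_search)


def write_subjects(df: pd.DataFrame, path) -> None:
    """Write a subject table; full float precision so round-trips are exact."""
    cols = [c for c in df.columns if c in _REQUIRED]
    df[cols].to_csv(path, index=False, float_format="%.17g")


# ---- scenario files ----------------------------------------------------


def _hazard_to_dict(h: PiecewiseHazard) -> dict:
    return {"breaks": h.breaks.tolist(), "rates": h.rates.tolist(),
            "cure": float(h.cure)}


def _hazard_from_dict(d: dict) -> PiecewiseHazard:
    return PiecewiseHazard(np.asarray(d["breaks"], dtype=float),
                           np.asarray(d["rates"], dtype=float),
                           float(d.get("cure", 0.0)))


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    return {
        "donor_fraction": float(spec.donor_fraction),
        "waiting_support": spec.waiting_support.tolist(),
        "waiting_probs": spec.waiting_probs.tolist(),
        "pre_hazard": _hazard_to_dict(spec.pre_hazard),
        "post_hazards": {str(w): _hazard_to_dict(h)
                         for w, h in spec.post_hazards.items()},
        "censor_range": list(spec.censor_range),
        "t_star": float(spec.t_star),
        "t_search": float(spec.t_search),
        "n": int(spec.n),
        "seed": int(spec.seed),
    }


def scenario_from_dict(d: dict) -> ScenarioSpec:
    return ScenarioSpec(
        donor_fraction=float(d["donor_fraction"]),
        waiting_support=np.asarray(d["waiting_support"], dtype=float),
        waiting_probs=np.asarray(d["waiting_probs"], dtype=float),
        pre_hazard=_hazard_from_dict(d["pre_hazard"]),
        post_hazards={float(w): _hazard_from_dict(h)
                      for w, h in d["post_hazards"].items()},
        censor_range=tuple(d["censor_range"]),
        t_star=float(d.get("t_star", 5.0)),
        t_search=float(d.get("t_search", 5.0)),
        n=int(d.get("n", 1000)),
        seed=int(d.get("seed", 0)),
    )


def load_scenario(path) -> ScenarioSpec:
    """Load a ScenarioSpec from a YAML or JSON file."""
    text = Path(path).read_text()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return scenario_from_dict(d)


def save_scenario(spec: ScenarioSpec, path) -> None:
    p = Path(path)
    d = scenario_to_dict(spec)
    if p.suffix == ".json":
        p.write_text(json.dumps(d, indent=2))
    else:
        p.write_text(yaml.safe_dump(d, sort_keys=False))
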