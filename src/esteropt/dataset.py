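"""Reference run table and run-table CSV I/O.

The packaged fixture is the published 48-run table of the esterquat
synthesis study: 30 training and 18 test runs from a five-factor central
composite design, each with the observed conversion% and the conversion%
the study's own neural network predicted.  The printed predictions are
carried only so the validation statistics can be recomputed against the
published values; they are never used as training targets.

Two design runs (16 and 42) were never published, so the 50-point design
yields a 48-row table.  Run 13's molar ratio is printed "2:2" — not an
r:1 level of the design — and is kept verbatim (scalar 1.0) with an
``anomaly`` flag rather than silently corrected.
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .doe import ReactionCondition

__all__ = [
    "CENTER_REPLICATE_RUNS",
    "ExperimentRecord",
    "load_reference",
    "read_runs",
    "write_runs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentRecord:
    """One experimental run: condition, observed conversion, split label."""

    run_id: int
    condition: ReactionCondition
    conversion_actual: float  #: observed conversion, % in [0, 100]
    split: str  #: "train" or "test"
    conversion_predicted_printed: Optional[float] = None  #: published model prediction
    anomaly: bool = False  #: condition as printed does not lie on the design lattice

    def __post_init__(self) -> None:
        if self.split not in ("train", "test"):
            raise ValueError(f"run {self.run_id}: split must be train/test, got {self.split!r}")
        if not (0.0 <= self.conversion_actual <= 100.0):
            raise ValueError(
                f"run {self.run_id}: conversion {self.conversion_actual} outside [0, 100]"
            )


#: Replicated center-point runs (all at enzyme 5, time 16 h, 60 °C, 2:1, 400 rpm).
CENTER_REPLICATE_RUNS = (1, 30, 32, 33, 43, 44, 48)

# Published run table, verbatim.  molar_ratio is the printed a:b string.
_REFERENCE_CSV = """\
run,enzyme,time,temperature,molar_ratio,agitation,actual,predicted,split
1,5,16,60,2:1,400,56.44,51.36,train
2,5,16,60,2:1,137.5,47.78,44.99,train
3,3,24,55,1:1,550,48.22,54.60,train
6,3,24,65,1:1,550,63.56,63.11,train
11,5,16,51.25,2:1,400,39.56,37.92,train
13,5,16,60,2:2,400,51.11,51.36,train
14,3,8,55,1:1,250,44.44,43.22,train
17,5,30,60,2:1,400,60.00,60.26,train
18,7,8,55,3:1,250,25.00,27.67,train
20,3,8,55,3:1,250,25.56,26.36,train
21,5,16,60,2:1,662.5,46.22,55.09,train
22,7,24,65,1:1,250,63.33,63.33,train
24,7,8,55,3:1,550,33.78,33.41,train
25,8.5,16,60,2:1,400,48.44,53.85,train
26,5,16,60,3.75:1,400,38.00,35.86,train
27,7,24,55,3:1,250,35.33,38.86,train
30,5,16,60,2:1,400,62.44,51.36,train
32,5,16,60,2:1,400,58.00,51.36,train
33,5,16,60,2:1,400,55.33,51.36,train
35,3,8,65,3:1,550,44.89,47.34,train
36,3,24,55,3:1,250,34.89,35.22,train
37,7,24,65,3:1,550,67.11,62.35,train
39,7,24,65,1:1,550,71.33,64.32,train
40,1.5,16,60,2:1,400,44.22,48.65,train
41,7,8,65,1:1,250,48.89,55.78,train
43,5,16,60,2:1,400,46.89,51.36,train
44,5,16,60,2:1,400,52.00,51.36,train
47,3,8,65,3:1,250,35.78,37.32,train
48,5,16,60,2:1,400,53.11,51.36,train
49,5,2,60,2:1,400,38.00,38.91,train
4,3,8,55,1:1,550,46.44,45.55,test
5,7,8,65,1:1,550,57.56,58.28,test
7,7,8,55,1:1,250,48.89,44.31,test
8,3,24,65,1:1,250,62.89,62.15,test
9,7,8,65,3:1,550,50.67,51.19,test
10,3,24,55,3:1,550,44.00,44.59,test
12,3,8,55,3:1,550,32.00,30.58,test
15,3,8,65,1:1,550,57.78,56.47,test
19,7,8,55,1:1,550,52.67,47.29,test
23,3,24,55,1:1,250,52.22,53.69,test
28,7,24,55,1:1,550,59.11,56.27,test
29,3,8,65,1:1,250,54.44,54.03,test
31,7,24,65,3:1,250,58.00,57.47,test
34,3,24,65,3:1,550,64.89,60.32,test
38,7,24,55,1:1,250,52.67,54.77,test
45,3,24,65,3:1,250,54.22,54.04,test
46,7,8,65,3:1,250,41.33,41.31,test
50,7,24,55,3:1,550,49.33,48.53,test
"""

# sha256 of _REFERENCE_CSV; guards against accidental edits of the fixture.
_REFERENCE_SHA256 = "41a8ab16c577a986e61db29d1a26f92f3b7c7760f1ac4b5c7357d69cd4559367"


def _ratio_scalar(raw: str) -> tuple[float, bool]:
    """Parse an "a:b" molar ratio into the scalar r of the r:1 convention.

    A ratio whose right-hand side is not 1 (the run-13 "2:2" misprint) is
    flagged as anomalous; its literal value a/b is kept.
    """
    left, _, right = str(raw).partition(":")
    a = float(left)
    b = float(right) if right else 1.0
    return a / b, b != 1.0


def load_reference() -> list[ExperimentRecord]:
    """Return the 48 published runs, verbatim, with their train/test labels."""
    digest = hashlib.sha256(_REFERENCE_CSV.encode()).hexdigest()
    if digest != _REFERENCE_SHA256:
        raise RuntimeError("reference run table is corrupted (checksum mismatch)")
    df = pd.read_csv(io.StringIO(_REFERENCE_CSV), dtype={"molar_ratio": str})
    records = []
    for _, r in df.iterrows():
        ratio, anomaly = _ratio_scalar(r["molar_ratio"])
        cond = ReactionCondition(
            enzyme=float(r["enzyme"]),
            time=float(r["time"]),
            temperature=float(r["temperature"]),
            molar_ratio=ratio,
            agitation=float(r["agitation"]),
        )
        records.append(
            ExperimentRecord(
                run_id=int(r["run"]),
                condition=cond,
                conversion_actual=float(r["actual"]),
                split=str(r["split"]),
                conversion_predicted_printed=float(r["predicted"]),
                anomaly=anomaly,
            )
        )
    return records


_RUN_COLUMNS = ["run", "enzyme", "time", "temperature", "molar_ratio", "agitation", "conversion", "split"]


def read_runs(path) -> list[ExperimentRecord]:
    """Read a run table CSV (molar_ratio as the r:1 scalar).

    Required columns: run, enzyme, time, temperature, molar_ratio,
    agitation, conversion, split.  Optional: predicted, anomaly.
    """
    df = pd.read_csv(path)
    if df.empty and not df.columns.size:
        logger.warning("run table %s is empty", path)
        return []
    missing = [c for c in _RUN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"run table {path}: missing columns {missing}")
    records = []
    for i, r in df.iterrows():
        rownum = i + 2  # 1-based, after header
        try:
            cond = ReactionCondition(
                enzyme=float(r["enzyme"]),
                time=float(r["time"]),
                temperature=float(r["temperature"]),
                molar_ratio=float(r["molar_ratio"]),
                agitation=float(r["agitation"]),
            )
            predicted = None
            if "predicted" in df.columns and pd.notna(r["predicted"]):
                predicted = float(r["predicted"])
            rec = ExperimentRecord(
                run_id=int(r["run"]),
                condition=cond,
                conversion_actual=float(r["conversion"]),
                split=str(r["split"]),
                conversion_predicted_printed=predicted,
                anomaly=bool(r["anomaly"]) if "anomaly" in df.columns else False,
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"run table {path}, row {rownum}: {exc}") from exc
        records.append(rec)
    if not records:
        logger.warning("run table %s has no data rows", path)
    run_ids = [rec.run_id for rec in records]
    if len(set(run_ids)) != len(run_ids):
        raise ValueError(f"run table {path}: duplicate run ids")
    return records


def write_runs(records: Iterable[ExperimentRecord], path) -> None:
    """Write a run table CSV; inverse of :func:`read_runs` on all fields."""
    records = list(records)
    rows = []
    for rec in records:
        c = rec.condition
        rows.append(
            {
                "run": rec.run_id,
                "enzyme": c.enzyme,
                "time": c.time,
                "temperature": c.temperature,
                "molar_ratio": c.molar_ratio,
                "agitation": c.agitation,
                "conversion": rec.conversion_actual,
                "split": rec.split,
                "predicted": rec.conversion_predicted_printed,
                "anomaly": rec.anomaly,
            }
        )
    pd.DataFrame(rows, columns=_RUN_COLUMNS + ["predicted", "anomaly"]).to_csv(path, index=False)


def split_records(
    records: Sequence[ExperimentRecord],
) -> tuple[list[ExperimentRecord], list[ExperimentRecord]]:
    """Partition records into (train, test) by their split labels."""
    train = [r for r in records if r.split == "train"]
    test = [r for r in records if r.split == "test"]
    return train, test
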