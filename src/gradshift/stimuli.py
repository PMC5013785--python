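"""Domain types for odour stimuli, conditioning designs and response tables.

The perceptual dimension throughout is aldehyde carbon-chain length: each
stimulus is identified by its integer number of carbon atoms (hexanal = 6
through nonanal = 9 in the study designs), and odour names are labels only.
Behavioural responses are stored as integer counts (ants tested, ants
showing the maxilla-labium extension response, MaLER); percentages are always
derived from the counts so that paired-count statistics remain computable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Odourant",
    "ExperimentDesign",
    "ResponseTable",
    "ALDEHYDES",
    "AGGREGATE_COLUMNS",
    "PER_ANT_COLUMNS",
    "load_responses",
    "write_responses",
    "load_per_ant",
    "write_per_ant",
    "pair_records",
]

#: The four aldehydes of the study, keyed by carbon-chain length.
ALDEHYDES = {6: "hexanal", 7: "heptanal", 8: "octanal", 9: "nonanal"}

AGGREGATE_COLUMNS = [
    "experiment_id",
    "protocol",
    "cs_plus_carbon",
    "cs_minus_carbon",
    "test_carbon",
    "n_tested",
    "n_responders",
]

PER_ANT_COLUMNS = [
    "experiment_id",
    "protocol",
    "ant_id",
    "phase",
    "trial_index",
    "stimulus_role",
    "test_carbon",
    "response",
]

_PROTOCOLS = ("absolute", "differential")


@dataclass(frozen=True)
class Odourant:
    """A stimulus identified by its carbon-chain length.

    Parameters
    ----------
    name : str
        Chemical label, e.g. ``"hexanal"``.
    carbon_position : int
        Number of carbon atoms; the coordinate on the generalization
        dimension.
    """

    name: str
    carbon_position: int

    def __post_init__(self) -> None:
        if not (isinstance(self.carbon_position, (int, np.integer)) and self.carbon_position > 0):
            raise ValueError(
                f"carbon_position must be a positive integer, got {self.carbon_position!r}"
            )

    @classmethod
    def from_position(cls, carbon_position: int) -> "Odourant":
        name = ALDEHYDES.get(int(carbon_position), f"C{int(carbon_position)}-aldehyde")
        return cls(name=name, carbon_position=int(carbon_position))


@dataclass(frozen=True)
class ExperimentDesign:
    """A conditioning design: CS+ (rewarded), optional CS- (punished), tests.

    ``protocol`` is ``"absolute"`` (single rewarded odour plus blank trials)
    or ``"differential"`` (rewarded CS+ interleaved with punished CS-).
    """

    experiment_id: str
    protocol: str
    cs_plus: int
    test_positions: tuple
    n_ants: int
    cs_minus: int | None = None

    def __post_init__(self) -> None:
        if self.protocol not in _PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}; expected one of {_PROTOCOLS}")
        if self.protocol == "absolute" and self.cs_minus is not None:
            raise ValueError("absolute conditioning has no CS-")
        if self.protocol == "differential":
            if self.cs_minus is None:
                raise ValueError("differential conditioning requires a CS-")
            if self.cs_minus == self.cs_plus:
                raise ValueError("CS- must differ from CS+")
        object.__setattr__(self, "test_positions", tuple(int(p) for p in self.test_positions))
        if self.cs_plus not in self.test_positions:
            raise ValueError("CS+ must be among the test positions")
        if self.cs_minus is not None and self.cs_minus not in self.test_positions:
            raise ValueError("CS- must be among the test positions")
        if self.n_ants < 1:
            raise ValueError("n_ants must be positive")


@dataclass(frozen=True)
class ResponseTable:
    """Per-test-odour response counts for one (experiment, protocol) group."""

    positions: tuple
    n_tested: tuple
    n_responders: tuple

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.positions)
        nt = tuple(int(n) for n in self.n_tested)
        nr = tuple(int(n) for n in self.n_responders)
        if not (len(pos) == len(nt) == len(nr)):
            raise ValueError("positions, n_tested and n_responders must have equal length")
        if len(set(pos)) != len(pos):
            raise ValueError(f"duplicate test positions: {pos}")
        for p, t, r in zip(pos, nt, nr):
            if t < 0 or r < 0 or r > t:
                raise ValueError(
                    f"invalid counts at test position {p}: n_responders={r}, n_tested={t}"
                )
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "n_tested", nt)
        object.__setattr__(self, "n_responders", nr)

    @property
    def pct(self) -> np.ndarray:
        """Response percentages, 100 * n_responders / n_tested."""
        nt = np.asarray(self.n_tested, dtype=float)
        nr = np.asarray(self.n_responders, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(nt > 0, 100.0 * nr / nt, np.nan)
        return out

    def pct_at(self, position: int) -> float:
        return float(self.pct[self.positions.index(int(position))])

    def sorted(self) -> "ResponseTable":
        order = np.argsort(self.positions)
        return ResponseTable(
            positions=tuple(self.positions[i] for i in order),
            n_tested=tuple(self.n_tested[i] for i in order),
            n_responders=tuple(self.n_responders[i] for i in order),
        )


def _records_to_frame(records: Iterable[tuple]) -> pd.DataFrame:
    rows = []
    for design, table in records:
        for p, t, r in zip(table.positions, table.n_tested, table.n_responders):
            rows.append(
                {
                    "experiment_id": design.experiment_id,
                    "protocol": design.protocol,
                    "cs_plus_carbon": design.cs_plus,
                    "cs_minus_carbon": "" if design.cs_minus is None else design.cs_minus,
                    "test_carbon": p,
                    "n_tested": t,
                    "n_responders": r,
                }
            )
    return pd.DataFrame(rows, columns=AGGREGATE_COLUMNS)


def write_responses(records: Sequence[tuple], path) -> None:
    """Write ``(ExperimentDesign, ResponseTable)`` pairs to the aggregate CSV.

    ``load_responses`` is the inverse: load(write(x)) == x for valid records.
    An empty record list yields a header-only file.
    """
    frame = _records_to_frame(records)
    frame.to_csv(path, index=False)


def load_responses(path) -> list:
    """Load the aggregate response CSV into ``(ExperimentDesign, ResponseTable)`` pairs.

    One pair per (experiment_id, protocol) group, sorted by experiment then
    protocol (absolute before differential). Percentages are derived from the
    counts. Malformed rows, duplicate (experiment, protocol, position) rows
    and count violations are rejected with a row-identifying message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"response file not found: {path}")
    frame = pd.read_csv(path, dtype={"experiment_id": str, "protocol": str})
    missing = [c for c in AGGREGATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if frame.empty:
        return []

    dup = frame.duplicated(subset=["experiment_id", "protocol", "test_carbon"], keep=False)
    if dup.any():
        bad = frame.loc[dup, ["experiment_id", "protocol", "test_carbon"]].iloc[0]
        raise ValueError(
            f"{path}: duplicate row for experiment={bad.experiment_id!r} "
            f"protocol={bad.protocol!r} test_carbon={bad.test_carbon}"
        )

    records = []
    for (exp_id, protocol), group in frame.groupby(["experiment_id", "protocol"], sort=True):
        if protocol not in _PROTOCOLS:
            raise ValueError(f"{path}: unknown protocol {protocol!r} in experiment {exp_id!r}")
        cs_plus_vals = group["cs_plus_carbon"].unique()
        if len(cs_plus_vals) != 1:
            raise ValueError(f"{path}: inconsistent cs_plus_carbon in ({exp_id!r}, {protocol!r})")
        cs_minus_raw = group["cs_minus_carbon"]
        if protocol == "absolute":
            if cs_minus_raw.notna().any() and (cs_minus_raw.astype(str).str.strip() != "").any():
                raise ValueError(
                    f"{path}: absolute record {exp_id!r} must leave cs_minus_carbon empty"
                )
            cs_minus = None
        else:
            vals = pd.to_numeric(cs_minus_raw, errors="coerce").dropna().unique()
            if len(vals) != 1:
                raise ValueError(
                    f"{path}: differential record {exp_id!r} needs one cs_minus_carbon value"
                )
            cs_minus = int(vals[0])

        for _, row in group.iterrows():
            if row["n_responders"] > row["n_tested"]:
                raise ValueError(
                    f"{path}: n_responders > n_tested for experiment={exp_id!r} "
                    f"protocol={protocol!r} test_carbon={row['test_carbon']}"
                )

        group = group.sort_values("test_carbon")
        n_tested = tuple(int(v) for v in group["n_tested"])
        design = ExperimentDesign(
            experiment_id=str(exp_id),
            protocol=str(protocol),
            cs_plus=int(cs_plus_vals[0]),
            cs_minus=cs_minus,
            test_positions=tuple(int(v) for v in group["test_carbon"]),
            n_ants=max(n_tested),
        )
        table = ResponseTable(
            positions=design.test_positions,
            n_tested=n_tested,
            n_responders=tuple(int(v) for v in group["n_responders"]),
        )
        records.append((design, table))
    return records


def pair_records(records: Sequence[tuple]) -> list:
    """Pair absolute and differential records sharing a CS+ for joint fitting.

    Returns a list of ``(abs_design, abs_table, diff_design, diff_table)``
    tuples, one per CS+ that appears in both an absolute and a differential
    record. Unpaired records are silently omitted (they cannot enter the
    joint eight-point fit).
    """
    absolute = {d.cs_plus: (d, t) for d, t in records if d.protocol == "absolute"}
    pairs = []
    for design, table in records:
        if design.protocol != "differential":
            continue
        if design.cs_plus in absolute:
            abs_design, abs_table = absolute[design.cs_plus]
            pairs.append((abs_design, abs_table, design, table))
    return pairs


def write_per_ant(frame: pd.DataFrame, path) -> None:
    """Write per-ant long-format records (one row per ant x event) to CSV."""
    missing = [c for c in PER_ANT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"per-ant frame missing columns {missing}")
    frame[PER_ANT_COLUMNS].to_csv(path, index=False)


def load_per_ant(path) -> pd.DataFrame:
    """Load the per-ant long-format CSV.

    Responses must be 0/1; ``phase`` is ``trial`` or ``test``. Test rows carry
    the test odour's carbon position in ``test_carbon``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"per-ant file not found: {path}")
    frame = pd.read_csv(path, dtype={"experiment_id": str, "protocol": str})
    missing = [c for c in PER_ANT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~frame["response"].isin([0, 1])
    if bad.any():
        raise ValueError(f"{path}: non-binary response values in rows {list(frame.index[bad][:5])}")
    if not frame["phase"].isin(["trial", "test"]).all():
        raise ValueError(f"{path}: phase must be 'trial' or 'test'")
    return frame
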