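"""Core data model for current-clamp sweeps, stimulus protocols and cohorts.

A :class:`Sweep` is one time-aligned pair of membrane-potential (mV) and
command-current (pA) traces sampled at a fixed interval, annotated with the
stimulus protocol that produced it.  A :class:`Cohort` bundles the per-cell
metadata (class, layer, anatomical position, inclusion criteria) with the
sweeps recorded from each cell.

Units are fixed package-wide: mV, pA, ms, MOhm, Hz, um (mediolateral
distance from the parasubiculum border) and mm (dorsoventral depth from
bregma).

On-disk formats are plain text: sweeps are tab-delimited three-column files
(``time_ms``, ``voltage_mV``, ``current_pA``) with a ``<stem>.meta`` sidecar
of ``key=value`` lines; cohort manifests are tab-delimited tables with one
row per cell.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolKind",
    "StimulusProtocol",
    "Sweep",
    "CellClass",
    "Layer",
    "CellRecord",
    "Cohort",
    "FormatError",
    "SamplingError",
    "is_included",
    "read_sweep",
    "write_sweep",
    "read_cohort",
    "write_cohort",
    "RESTING_VM_CUTOFF_MV",
    "SERIES_RESISTANCE_CUTOFF_MOHM",
]

#: Inclusion criteria for recorded cells: resting Vm <= -50 mV and
#: series resistance <= 50 MOhm.
RESTING_VM_CUTOFF_MV = -50.0
SERIES_RESISTANCE_CUTOFF_MOHM = 50.0

#: Default sampling interval for simulated sweeps (20 kHz).
DEFAULT_TIME_STEP_MS = 0.05


class FormatError(ValueError):
    """A sweep or manifest file does not conform to the expected layout."""


class SamplingError(ValueError):
    """The time base of a sweep file is not uniform."""


class ProtocolKind(str, Enum):
    CURRENT_STEP = "current_step"
    CURRENT_RAMP = "current_ramp"
    ZAP = "zap"
    OPTO_PULSE = "opto_pulse"
    OPTO_TRAIN = "opto_train"
    PAIRED_AP = "paired_ap"
    NONE = "none"


#: Train frequencies for which inter-pulse measurement windows are defined.
TRAIN_FREQUENCIES_HZ = (10.0, 20.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulus annotation for one sweep.

    ``parameters`` holds kind-specific values, all floats:

    - current_step: ``amplitude_pA``, ``duration_ms``
    - current_ramp: ``slope_pA_per_s``, ``duration_ms``
    - zap: ``f0_hz``, ``f1_hz``, ``duration_ms``, ``amplitude_pA``
    - opto_pulse: ``pulse_width_ms``
    - opto_train: ``pulse_width_ms``, ``frequency_hz``, ``n_pulses``
    - paired_ap: ``amplitude_pA``, ``pulse_width_ms``
    """

    kind: ProtocolKind = ProtocolKind.NONE
    onset_ms: float = 0.0
    parameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.onset_ms < 0:
            raise ValueError(f"onset_ms must be >= 0, got {self.onset_ms}")
        if self.kind is ProtocolKind.OPTO_TRAIN:
            freq = self.parameters.get("frequency_hz")
            if freq is not None and float(freq) not in TRAIN_FREQUENCIES_HZ:
                raise ValueError(
                    f"opto_train frequency must be one of {TRAIN_FREQUENCIES_HZ} Hz, "
                    f"got {freq}"
                )

    def param(self, key: str) -> float:
        try:
            return float(self.parameters[key])
        except KeyError:
            raise KeyError(
                f"protocol {self.kind.value!r} is missing parameter {key!r}"
            ) from None


@dataclass
class Sweep:
    """One voltage/current trace pair on a uniform time base."""

    time_step: float  # ms per sample
    voltage: np.ndarray  # mV
    current: np.ndarray  # pA
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    sweep_index: int = 0
    cell_id: str = ""
    condition: str = "baseline"

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time_step <= 0:
            raise ValueError(f"time_step must be > 0, got {self.time_step}")
        if self.voltage.ndim != 1 or self.current.ndim != 1:
            raise FormatError("voltage and current must be 1-D")
        if len(self.voltage) != len(self.current):
            raise FormatError(
                f"voltage ({len(self.voltage)}) and current ({len(self.current)}) "
                "lengths differ"
            )
        if len(self.voltage) < 2:
            raise FormatError("sweep must contain at least 2 samples")
        if not (np.isfinite(self.voltage).all() and np.isfinite(self.current).all()):
            raise FormatError("sweep contains non-finite samples")
        if self.sweep_index < 0:
            raise ValueError("sweep_index must be non-negative")
        if self.protocol.onset_ms > self.duration_ms:
            raise ValueError(
                f"protocol onset {self.protocol.onset_ms} ms is beyond sweep "
                f"duration {self.duration_ms} ms"
            )

    @property
    def n_samples(self) -> int:
        return len(self.voltage)

    @property
    def duration_ms(self) -> float:
        return (len(self.voltage) - 1) * self.time_step

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.voltage)) * self.time_step

    def index_at(self, t_ms: float) -> int:
        """Index of the sample at or immediately after time ``t_ms``."""
        return int(np.ceil(t_ms / self.time_step - 1e-9))


class CellClass(str, Enum):
    L2_SC = "L2_SC"
    L2_PC = "L2_PC"
    L3_PC = "L3_PC"
    L5A_PC = "L5a_PC"
    L5B_PC = "L5b_PC"
    L1_IN = "L1_IN"
    L2_IN_FS = "L2_IN_FS"
    L2_IN_LTS = "L2_IN_LTS"


class Layer(str, Enum):
    L1 = "L1"
    L2 = "L2"
    L3 = "L3"
    L5A = "L5a"
    L5B = "L5b"


CLASS_LAYER: Dict[CellClass, Layer] = {
    CellClass.L2_SC: Layer.L2,
    CellClass.L2_PC: Layer.L2,
    CellClass.L3_PC: Layer.L3,
    CellClass.L5A_PC: Layer.L5A,
    CellClass.L5B_PC: Layer.L5B,
    CellClass.L1_IN: Layer.L1,
    CellClass.L2_IN_FS: Layer.L2,
    CellClass.L2_IN_LTS: Layer.L2,
}


def is_included(resting_vm_mV: float, series_resistance_MOhm: float) -> bool:
    """Inclusion rule: resting Vm <= -50 mV and series resistance <= 50 MOhm."""
    return (
        resting_vm_mV <= RESTING_VM_CUTOFF_MV
        and series_resistance_MOhm <= SERIES_RESISTANCE_CUTOFF_MOHM
    )


@dataclass
class CellRecord:
    cell_id: str
    cell_class: CellClass
    ml_distance_um: float  # soma distance from the parasubiculum border, >= 0
    dv_depth_mm: float  # slice depth ventral to bregma
    resting_vm_mV: float
    series_resistance_MOhm: float
    layer: Optional[Layer] = None
    included: bool = field(init=False)

    def __post_init__(self) -> None:
        self.cell_class = CellClass(self.cell_class)
        expected = CLASS_LAYER[self.cell_class]
        if self.layer is None:
            self.layer = expected
        else:
            self.layer = Layer(self.layer)
            if self.layer is not expected:
                raise ValueError(
                    f"cell {self.cell_id}: class {self.cell_class.value} implies "
                    f"layer {expected.value}, got {self.layer.value}"
                )
        if self.ml_distance_um < 0:
            raise ValueError("ml_distance_um must be >= 0")
        self.included = is_included(self.resting_vm_mV, self.series_resistance_MOhm)


@dataclass
class Cohort:
    """A set of recorded cells and their sweeps."""

    cells: List[CellRecord] = field(default_factory=list)
    sweeps: Dict[str, List[Sweep]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {c.cell_id for c in self.cells}
        if len(ids) != len(self.cells):
            raise ValueError("duplicate cell_id in cohort")
        for cid, swps in self.sweeps.items():
            if cid not in ids:
                raise ValueError(f"sweeps recorded for unknown cell {cid!r}")
            seen = set()
            for s in swps:
                key = (s.protocol.kind, s.condition, s.sweep_index)
                if key in seen:
                    raise ValueError(
                        f"cell {cid!r}: duplicate sweep index {s.sweep_index} for "
                        f"{s.protocol.kind.value}/{s.condition}"
                    )
                seen.add(key)

    def cell(self, cell_id: str) -> CellRecord:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)

    def cell_sweeps(
        self,
        cell_id: str,
        kind: Optional[ProtocolKind] = None,
        condition: Optional[str] = None,
    ) -> List[Sweep]:
        out = []
        for s in self.sweeps.get(cell_id, []):
            if kind is not None and s.protocol.kind is not kind:
                continue
            if condition is not None and s.condition != condition:
                continue
            out.append(s)
        return out

    @property
    def included_cells(self) -> List[CellRecord]:
        return [c for c in self.cells if c.included]


# ---------------------------------------------------------------------------
# Sweep file IO
# ---------------------------------------------------------------------------

_SWEEP_COLUMNS = ("time_ms", "voltage_mV", "current_pA")


def write_sweep(sweep: Sweep, path: os.PathLike | str) -> Path:
    """Write a sweep as a tab-delimited text file plus a ``.meta`` sidecar."""
    path = Path(path)
    data = np.column_stack([sweep.time_ms, sweep.voltage, sweep.current])
    np.savetxt(
        path,
        data,
        fmt="%.10g",
        delimiter="\t",
        header="\t".join(_SWEEP_COLUMNS),
        comments="",
    )
    meta_lines = [
        f"cell_id={sweep.cell_id}",
        f"condition={sweep.condition}",
        f"sweep_index={sweep.sweep_index}",
        f"time_step_ms={sweep.time_step!r}",
        f"protocol.kind={sweep.protocol.kind.value}",
        f"protocol.onset_ms={sweep.protocol.onset_ms!r}",
    ]
    for key in sorted(sweep.protocol.parameters):
        meta_lines.append(f"protocol.{key}={float(sweep.protocol.parameters[key])!r}")
    sidecar_path(path).write_text("\n".join(meta_lines) + "\n")
    return path


def sidecar_path(path: os.PathLike | str) -> Path:
    return Path(path).with_suffix(".meta")


def _read_sidecar(path: Path) -> dict:
    meta = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}: malformed sidecar line {line!r}")
        key, value = line.split("=", 1)
        meta[key.strip()] = value.strip()
    return meta


def read_sweep(path: os.PathLike | str) -> Sweep:
    """Read a sweep file written by :func:`write_sweep`.

    The time column is verified to be uniform to within 1e-6 relative
    tolerance and collapsed to a scalar ``time_step``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t")
    for col in _SWEEP_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    time = table["time_ms"].to_numpy(dtype=float)
    if len(time) < 2:
        raise FormatError(f"{path}: fewer than 2 samples")
    steps = np.diff(time)
    step = steps[0]
    if step <= 0 or np.any(np.abs(steps - step) > 1e-6 * max(abs(step), 1.0)):
        raise SamplingError(f"{path}: non-uniform time base")

    meta_path = sidecar_path(path)
    if not meta_path.exists():
        raise FormatError(f"{path}: missing sidecar {meta_path.name}")
    meta = _read_sidecar(meta_path)
    params = {
        key[len("protocol."):]: float(value)
        for key, value in meta.items()
        if key.startswith("protocol.") and key not in ("protocol.kind", "protocol.onset_ms")
    }
    protocol = StimulusProtocol(
        kind=ProtocolKind(meta.get("protocol.kind", "none")),
        onset_ms=float(meta.get("protocol.onset_ms", 0.0)),
        parameters=params,
    )
    time_step = float(meta["time_step_ms"]) if "time_step_ms" in meta else float(step)
    if abs(time_step - step) > 1e-6 * max(abs(step), 1.0):
        raise SamplingError(
            f"{path}: sidecar time_step_ms {time_step} disagrees with time column"
        )
    return Sweep(
        time_step=time_step,
        voltage=table["voltage_mV"].to_numpy(dtype=float),
        current=table["current_pA"].to_numpy(dtype=float),
        protocol=protocol,
        sweep_index=int(meta.get("sweep_index", 0)),
        cell_id=meta.get("cell_id", ""),
        condition=meta.get("condition", "baseline"),
    )


# ---------------------------------------------------------------------------
# Cohort IO
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = (
    "cell_id",
    "cell_class",
    "layer",
    "ml_distance_um",
    "dv_depth_mm",
    "resting_vm_mV",
    "series_resistance_MOhm",
)


def write_cohort(cohort: Cohort, manifest: os.PathLike | str,
                 sweep_dir: os.PathLike | str) -> Path:
    """Write a cohort manifest plus one sweep file per sweep under sweep_dir."""
    manifest = Path(manifest)
    sweep_dir = Path(sweep_dir)
    sweep_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "cell_id": c.cell_id,
            "cell_class": c.cell_class.value,
            "layer": c.layer.value,
            "ml_distance_um": c.ml_distance_um,
            "dv_depth_mm": c.dv_depth_mm,
            "resting_vm_mV": c.resting_vm_mV,
            "series_resistance_MOhm": c.series_resistance_MOhm,
        }
        for c in cohort.cells
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(
        manifest, sep="\t", index=False
    )
    for cid, swps in cohort.sweeps.items():
        for s in swps:
            name = f"{cid}__{s.protocol.kind.value}__{s.condition}__{s.sweep_index}.tsv"
            write_sweep(s, sweep_dir / name)
    return manifest


def read_cohort(manifest: os.PathLike | str,
                sweep_dir: Optional[os.PathLike | str] = None) -> Cohort:
    """Read a cohort manifest and, optionally, all sweep files under sweep_dir.

    Cells failing the inclusion criteria are retained with ``included=False``.
    Sweep files whose cell_id does not appear in the manifest produce a
    warning, not an error.
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise FileNotFoundError(manifest)
    table = pd.read_csv(manifest, sep="\t")
    for col in _MANIFEST_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"{manifest}: missing column {col!r}")
    cells = []
    for _, row in table.iterrows():
        try:
            cell_class = CellClass(row["cell_class"])
        except ValueError:
            raise FormatError(
                f"{manifest}: unknown cell_class {row['cell_class']!r} "
                f"for cell {row['cell_id']!r}"
            ) from None
        cells.append(
            CellRecord(
                cell_id=str(row["cell_id"]),
                cell_class=cell_class,
                layer=Layer(row["layer"]),
                ml_distance_um=float(row["ml_distance_um"]),
                dv_depth_mm=float(row["dv_depth_mm"]),
                resting_vm_mV=float(row["resting_vm_mV"]),
                series_resistance_MOhm=float(row["series_resistance_MOhm"]),
            )
        )
    known = {c.cell_id for c in cells}
    sweeps: Dict[str, List[Sweep]] = {}
    if sweep_dir is not None:
        sweep_dir = Path(sweep_dir)
        for path in sorted(sweep_dir.glob("*.tsv")):
            s = read_sweep(path)
            if s.cell_id not in known:
                warnings.warn(
                    f"orphan sweep file {path.name}: cell {s.cell_id!r} not in manifest"
                )
                continue
            sweeps.setdefault(s.cell_id, []).append(s)
    return Cohort(cells=cells, sweeps=sweeps)
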