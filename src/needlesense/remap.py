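"""Impedance-to-conductivity remapping calibrated on saline solutions.

A concentric-electrode probe measures impedance magnitude ``|Z|`` (ohm) at 15
fixed excitation frequencies between 1 and 349 kHz.  Because manufacturing
tolerances shift the raw impedance, spectra are remapped per frequency onto a
calibration curve built from saline solutions of known conductivity: at each
frequency the (|Z_S|, sigma_S) node pairs define a monotone decreasing
piecewise-linear function, evaluated at the measured |Z| to yield a
conductivity feature in microsiemens per centimetre.

Only the impedance *magnitude* is handled; the analyzer's real/imaginary
decomposition is out of scope.  Units are fixed at ohm and uS/cm throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .errors import CalibrationError, FormatError, ValidationError

__all__ = [
    "DEFAULT_FREQS_KHZ",
    "N_FREQS",
    "FrequencyGrid",
    "ImpedanceSpectrum",
    "RemapTable",
    "ConductivitySpectrum",
    "build_remap_table",
    "remap_spectrum",
    "impedance_at_conductivity",
    "read_remap_table",
    "write_remap_table",
    "default_remap_table",
]

#: The fixed excitation-frequency grid of the analyzer, in kHz.
DEFAULT_FREQS_KHZ: tuple[float, ...] = (
    1, 2, 3, 7, 11, 17, 23, 31, 43, 61, 89, 127, 179, 251, 349,
)
N_FREQS = 15


def _as_float_array(values: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered excitation frequencies (kHz) of a full impedance sweep."""

    freqs_khz: tuple[float, ...] = DEFAULT_FREQS_KHZ

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.freqs_khz)
        object.__setattr__(self, "freqs_khz", freqs)
        if len(freqs) != N_FREQS:
            raise ValidationError(
                f"frequency grid must have exactly {N_FREQS} entries, got {len(freqs)}"
            )
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValidationError("frequency grid must be strictly increasing")

    def __len__(self) -> int:
        return N_FREQS

    def index_of(self, freq_khz: float) -> int:
        """Index of an exact grid frequency; raises if absent."""
        try:
            return self.freqs_khz.index(float(freq_khz))
        except ValueError:
            raise ValidationError(f"{freq_khz} kHz is not on the grid") from None


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """One full sweep of impedance magnitudes |Z| (ohm) on a frequency grid."""

    grid: FrequencyGrid
    z_ohm: np.ndarray

    def __post_init__(self) -> None:
        z = _as_float_array(self.z_ohm, "z_ohm")
        object.__setattr__(self, "z_ohm", z)
        if len(z) != len(self.grid):
            raise ValidationError(
                f"spectrum has {len(z)} values for a {len(self.grid)}-point grid"
            )
        if not np.all(np.isfinite(z)):
            raise ValidationError("impedance values must be finite")
        if np.any(z <= 0):
            raise ValidationError("impedance values must be positive")


@dataclass(frozen=True)
class ConductivitySpectrum:
    """Remapped conductivity features sigma (uS/cm), the classifier input.

    ``out_of_range`` flags frequencies where |Z| fell outside the calibration
    nodes and the output was clamped to the nearest node conductivity.
    """

    grid: FrequencyGrid
    sigma_us_cm: np.ndarray
    out_of_range: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sigma = _as_float_array(self.sigma_us_cm, "sigma_us_cm")
        object.__setattr__(self, "sigma_us_cm", sigma)
        if len(sigma) != len(self.grid):
            raise ValidationError("conductivity length does not match grid")
        if not np.all(np.isfinite(sigma)) or np.any(sigma < 0):
            raise ValidationError("conductivities must be finite and non-negative")
        oor = self.out_of_range
        oor = np.zeros(len(sigma), dtype=bool) if oor is None else np.asarray(oor, bool)
        if oor.shape != sigma.shape:
            raise ValidationError("out_of_range mask shape mismatch")
        object.__setattr__(self, "out_of_range", oor)

    @property
    def any_out_of_range(self) -> bool:
        return bool(self.out_of_range.any())


@dataclass(frozen=True)
class RemapTable:
    """Saline calibration nodes: 8 conductivities x 15 per-frequency impedances.

    ``conductivities_us_cm`` is strictly increasing across concentrations;
    every ``node_impedance_ohm`` row is strictly decreasing (higher
    conductivity pairs with lower impedance).
    """

    grid: FrequencyGrid
    conductivities_us_cm: np.ndarray
    node_impedance_ohm: np.ndarray

    def __post_init__(self) -> None:
        cond = _as_float_array(self.conductivities_us_cm, "conductivities_us_cm")
        node = np.asarray(self.node_impedance_ohm, dtype=float)
        object.__setattr__(self, "conductivities_us_cm", cond)
        object.__setattr__(self, "node_impedance_ohm", node)
        if np.any(np.diff(cond) <= 0):
            raise CalibrationError("conductivities must be strictly increasing")
        if np.any(cond <= 0):
            raise CalibrationError("conductivities must be positive")
        if node.shape != (len(self.grid), len(cond)):
            raise FormatError(
                f"node impedance matrix must be {len(self.grid)}x{len(cond)}, "
                f"got {node.shape}"
            )
        if not np.all(np.isfinite(node)) or np.any(node <= 0):
            raise CalibrationError("node impedances must be finite and positive")
        for i, freq in enumerate(self.grid.freqs_khz):
            if np.any(np.diff(node[i]) >= 0):
                raise CalibrationError(
                    f"node impedances not strictly decreasing at {freq:g} kHz"
                )

    @property
    def n_concentrations(self) -> int:
        return len(self.conductivities_us_cm)


def build_remap_table(
    saline_measurements: Sequence[Sequence[ImpedanceSpectrum]],
    conductivities_us_cm: Sequence[float],
    grid: FrequencyGrid | None = None,
) -> RemapTable:
    """Build a calibration table from repeated saline measurements.

    ``saline_measurements[c]`` holds the spectra recorded in the saline bath
    of conductivity ``conductivities_us_cm[c]``; the node impedance at each
    frequency is the per-frequency median over that bath's samples.
    """
    cond = _as_float_array(conductivities_us_cm, "conductivities_us_cm")
    if len(saline_measurements) != len(cond):
        raise ValidationError(
            f"{len(saline_measurements)} measurement groups for {len(cond)} conductivities"
        )
    if any(len(group) == 0 for group in saline_measurements):
        raise ValidationError("every concentration needs at least one spectrum")
    if grid is None:
        grid = saline_measurements[0][0].grid
    for group in saline_measurements:
        for spec in group:
            if spec.grid != grid:
                raise FormatError("all saline spectra must share one frequency grid")
    medians = np.column_stack(
        [np.median(np.stack([s.z_ohm for s in group]), axis=0)
         for group in saline_measurements]
    )
    for i, freq in enumerate(grid.freqs_khz):
        if np.any(np.diff(medians[i]) >= 0):
            raise CalibrationError(
                f"median impedances not strictly decreasing with conductivity "
                f"at {freq:g} kHz"
            )
    return RemapTable(grid=grid, conductivities_us_cm=cond, node_impedance_ohm=medians)


def remap_spectrum(
    spec: ImpedanceSpectrum,
    table: RemapTable,
    log_axes: bool = False,
) -> ConductivitySpectrum:
    """Remap an impedance spectrum to a conductivity spectrum.

    Per frequency, the (|Z_S|, sigma_S) nodes are linearly interpolated at the
    measured |Z|.  Queries outside the node range are clamped to the nearest
    node conductivity and flagged in ``out_of_range`` (never silently
    extrapolated).  ``log_axes=True`` interpolates in (log |Z|, log sigma)
    instead; off by default.
    """
    if spec.grid != table.grid:
        raise FormatError("spectrum and table are on different frequency grids")
    sigma = np.empty(N_FREQS)
    oor = np.empty(N_FREQS, dtype=bool)
    cond = table.conductivities_us_cm
    for i in range(N_FREQS):
        z_nodes = table.node_impedance_ohm[i]
        z = spec.z_ohm[i]
        # relative tolerance so float round-trips at the node edges don't flag
        oor[i] = (z < z_nodes[-1] * (1 - 1e-9)) or (z > z_nodes[0] * (1 + 1e-9))
        # np.interp needs ascending x: impedance rows descend, so reverse.
        x = z_nodes[::-1]
        y = cond[::-1]
        if log_axes:
            sigma[i] = float(np.exp(np.interp(np.log(z), np.log(x), np.log(y))))
        else:
            sigma[i] = float(np.interp(z, x, y))
    return ConductivitySpectrum(grid=spec.grid, sigma_us_cm=sigma, out_of_range=oor)


def impedance_at_conductivity(
    table: RemapTable, sigma_us_cm: Sequence[float] | float
) -> np.ndarray:
    """Inverse query: node-interpolated |Z| for target conductivities.

    ``sigma_us_cm`` is either a scalar (same target at all 15 frequencies) or
    one target per frequency.  Targets must lie within the table's
    conductivity range.  Used by the phantom generator to anchor tissue
    templates at physical conductivities.
    """
    sigma = np.broadcast_to(np.asarray(sigma_us_cm, float), (N_FREQS,)).copy()
    cond = table.conductivities_us_cm
    if np.any(sigma < cond[0]) or np.any(sigma > cond[-1]):
        raise ValidationError(
            f"target conductivity outside calibration range "
            f"[{cond[0]:g}, {cond[-1]:g}] uS/cm"
        )
    z = np.empty(N_FREQS)
    for i in range(N_FREQS):
        # sigma ascending vs impedance descending: interp on the sigma axis.
        z[i] = float(np.interp(sigma[i], cond, table.node_impedance_ohm[i]))
    return z


# ---------------------------------------------------------------------------
# Calibration-table file format (owned here; re-exported by io_cli)
#
#   COND,<s1>,...,<s8>
#   <freq_khz>,<z1>,...,<z8>     (15 rows)
# ---------------------------------------------------------------------------

def _parse_floats(fields: list[str], lineno: int) -> list[float]:
    out = []
    for f in fields:
        try:
            out.append(float(f))
        except ValueError:
            raise FormatError(f"line {lineno}: non-numeric field {f!r}") from None
    return out


def read_remap_table(source) -> RemapTable:
    """Read a calibration table from a path or text file object."""
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "<stream>")
    else:
        name = str(source)
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{name}: empty calibration file")
    head = lines[0].split(",")
    if head[0].strip().upper() != "COND":
        raise FormatError(f"{name}: line 1: expected 'COND' header row")
    cond = _parse_floats([f.strip() for f in head[1:]], 1)
    ncol = len(cond)
    freqs, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in ln.split(",")]
        if len(fields) != ncol + 1:
            raise FormatError(
                f"{name}: line {lineno}: expected {ncol + 1} columns, got {len(fields)}"
            )
        values = _parse_floats(fields, lineno)
        freqs.append(values[0])
        rows.append(values[1:])
    try:
        grid = FrequencyGrid(tuple(freqs))
        return RemapTable(
            grid=grid,
            conductivities_us_cm=np.array(cond),
            node_impedance_ohm=np.array(rows),
        )
    except (ValidationError, CalibrationError, FormatError) as exc:
        raise type(exc)(f"{name}: {exc}") from None


def _format_num(x: float) -> str:
    return f"{x:g}" if x != int(x) else str(int(x))


def write_remap_table(table: RemapTable, dest) -> None:
    """Write a calibration table; deterministic, round-trips exactly."""
    buf = io.StringIO()
    buf.write("COND," + ",".join(_format_num(c) for c in table.conductivities_us_cm))
    buf.write("\n")
    for i, freq in enumerate(table.grid.freqs_khz):
        row = ",".join(_format_num(z) for z in table.node_impedance_ohm[i])
        buf.write(f"{_format_num(freq)},{row}\n")
    if hasattr(dest, "write"):
        dest.write(buf.getvalue())
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())


@lru_cache(maxsize=1)
def default_remap_table() -> RemapTable:
    """The packaged default calibration table (8 saline baths x 15 freqs)."""
    with resources.files("needlesense.data").joinpath("remap_table.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return read_remap_table(fh)
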