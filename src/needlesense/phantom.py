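"""Synthetic layered-tissue phantom: templates, datasets, depth-indexed spectra.

Stands in for ex vivo measurements.  Each tissue class is a log-normal
template over the 15-point impedance sweep: per-frequency mean and dispersion
of log |Z|.  Multiplicative sensor noise keeps impedances positive.  A
phantom stack is an ordered list of tissue layers with thicknesses; a virtual
needle queries the spectrum at any depth, with an optional log-linear blend
zone around layer interfaces.

The cerebrospinal-fluid template is anchored to the calibration table's
16,000 uS/cm saline column (a saline-filled balloon in the physical phantom)
and carries zero dispersion; skin/fat/ligament templates are repo-defined
conductivity anchors inverted through the calibration table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bnn import CLASSES, encode_labels
from .errors import ConfigError, ValidationError
from .remap import (
    N_FREQS,
    ConductivitySpectrum,
    FrequencyGrid,
    ImpedanceSpectrum,
    RemapTable,
    default_remap_table,
    impedance_at_conductivity,
    remap_spectrum,
)

__all__ = [
    "TissueTemplate",
    "PhantomStack",
    "Layer",
    "LabeledDataset",
    "DEFAULT_STACK",
    "sample_spectrum",
    "generate_dataset",
    "spectrum_at_depth",
    "default_templates",
    "remap_features",
    "bayes_classify",
]

# Conductivity anchors (uS/cm) at the lowest/highest grid frequency; tissue
# conductivity rises with excitation frequency.  Repo-defined constants.
_TEMPLATE_ANCHORS: dict[str, tuple[float, float, float]] = {
    # tissue: (sigma at 1 kHz, sigma at 349 kHz, log-impedance dispersion)
    # fat's high-frequency anchor keeps >= 6 sd of headroom below the
    # distilled-water node at 349 kHz so tail draws stay remappable
    "fat": (150.0, 700.0, 0.035),
    "skin": (1200.0, 3200.0, 0.035),
    "ligament": (4300.0, 8300.0, 0.045),
}


@dataclass(frozen=True)
class TissueTemplate:
    """Log-normal impedance template of one tissue class."""

    tissue: str
    log_z_mean: np.ndarray
    log_z_sd: np.ndarray
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)

    def __post_init__(self) -> None:
        mean = np.asarray(self.log_z_mean, float)
        sd = np.asarray(self.log_z_sd, float)
        object.__setattr__(self, "log_z_mean", mean)
        object.__setattr__(self, "log_z_sd", sd)
        if mean.shape != (len(self.grid),) or sd.shape != (len(self.grid),):
            raise ValidationError("template arrays must match the grid length")
        if not np.all(np.isfinite(mean)):
            raise ValidationError("template means must be finite")
        if np.any(sd < 0) or not np.all(np.isfinite(sd)):
            raise ValidationError("template dispersions must be finite and >= 0")


@dataclass(frozen=True)
class Layer:
    tissue: str
    thickness_mm: float

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValidationError(
                f"layer {self.tissue!r}: thickness must be positive, "
                f"got {self.thickness_mm}"
            )


@dataclass(frozen=True)
class PhantomStack:
    """Ordered tissue layers the virtual needle penetrates, top to bottom."""

    layers: tuple[Layer, ...]
    boundary_blend_mm: float = 0.3

    def __post_init__(self) -> None:
        layers = tuple(
            l if isinstance(l, Layer) else Layer(*l) for l in self.layers
        )
        object.__setattr__(self, "layers", layers)
        if not layers:
            raise ValidationError("stack needs at least one layer")
        if self.boundary_blend_mm < 0:
            raise ValidationError("boundary_blend_mm must be >= 0")

    @property
    def total_depth_mm(self) -> float:
        return float(sum(l.thickness_mm for l in self.layers))

    @property
    def boundaries_mm(self) -> np.ndarray:
        """Cumulative entry depths: boundaries_mm[i] is the top of layer i."""
        t = np.array([l.thickness_mm for l in self.layers])
        return np.concatenate([[0.0], np.cumsum(t)])

    def layer_index_at(self, depth_mm: float) -> int:
        """Layer containing ``depth_mm``; intervals are right-open except the last."""
        if depth_mm < 0 or depth_mm > self.total_depth_mm:
            raise ValidationError(
                f"depth {depth_mm} mm outside stack [0, {self.total_depth_mm}]"
            )
        bounds = self.boundaries_mm
        idx = int(np.searchsorted(bounds, depth_mm, side="right")) - 1
        return min(idx, len(self.layers) - 1)

    def entry_depth_mm(self, layer_index: int) -> float:
        return float(self.boundaries_mm[layer_index])

    def first_layer_of(self, tissue: str) -> int:
        for i, layer in enumerate(self.layers):
            if layer.tissue == tissue:
                return i
        raise ValidationError(f"stack has no {tissue!r} layer")


#: Default lumbar-puncture path: skin, subcutaneous fat, ligament,
#: epidural fat, CSF (dorsal CSF width 2-3 mm).
DEFAULT_STACK = PhantomStack(
    layers=(
        Layer("skin", 3.0),
        Layer("fat", 10.0),
        Layer("ligament", 15.0),
        Layer("fat", 4.0),
        Layer("csf", 3.0),
    ),
    boundary_blend_mm=0.3,
)


@dataclass(frozen=True)
class LabeledDataset:
    """Spectra with tissue labels; the classifier's training/evaluation unit."""

    spectra: tuple[ImpedanceSpectrum, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "spectra", tuple(self.spectra))
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.spectra) != len(self.labels):
            raise ValidationError("spectra/labels length mismatch")
        if not self.spectra:
            raise ValidationError("dataset has no samples")
        encode_labels(self.labels)  # labels must be in the class set

    def __len__(self) -> int:
        return len(self.spectra)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for lab in self.labels:
            counts[lab.lower()] += 1
        return counts


#: Sample counts of the reference soft-tissue dataset.
DEFAULT_COUNTS: dict[str, int] = {"skin": 150, "fat": 81, "ligament": 149, "csf": 146}


def default_templates(table: RemapTable | None = None) -> dict[str, TissueTemplate]:
    """The shipped tissue templates, anchored to a calibration table.

    CSF is the table's highest-conductivity saline column exactly (zero
    dispersion: the physical stand-in is a saline-filled balloon); the other
    tissues are conductivity anchors inverted through the table, dispersion
    in log-impedance.
    """
    table = table or default_remap_table()
    grid = table.grid
    freqs = np.array(grid.freqs_khz)
    log_f = (np.log(freqs) - np.log(freqs[0])) / (np.log(freqs[-1]) - np.log(freqs[0]))
    templates: dict[str, TissueTemplate] = {}
    for tissue, (sig_lo, sig_hi, disp) in _TEMPLATE_ANCHORS.items():
        sigma = np.exp(np.log(sig_lo) + log_f * (np.log(sig_hi) - np.log(sig_lo)))
        z = impedance_at_conductivity(table, sigma)
        templates[tissue] = TissueTemplate(
            tissue=tissue,
            log_z_mean=np.log(z),
            log_z_sd=np.full(N_FREQS, disp),
            grid=grid,
        )
    templates["csf"] = TissueTemplate(
        tissue="csf",
        log_z_mean=np.log(table.node_impedance_ohm[:, -1]),
        log_z_sd=np.zeros(N_FREQS),
        grid=grid,
    )
    return {c: templates[c] for c in CLASSES}


def sample_spectrum(
    template: TissueTemplate, seed: int | np.random.Generator = 0
) -> ImpedanceSpectrum:
    """Draw one spectrum: |Z| = exp(N(log_z_mean, log_z_sd^2)) per frequency."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log_z = template.log_z_mean + template.log_z_sd * rng.standard_normal(N_FREQS)
    return ImpedanceSpectrum(grid=template.grid, z_ohm=np.exp(log_z))


def generate_dataset(
    templates: Mapping[str, TissueTemplate],
    counts: Mapping[str, int] | None = None,
    seed: int = 0,
) -> LabeledDataset:
    """Generate a shuffled labeled dataset with exact per-class counts."""
    counts = dict(counts) if counts is not None else dict(DEFAULT_COUNTS)
    for tissue, n in counts.items():
        if tissue not in templates:
            raise ConfigError(f"no template for class {tissue!r}")
        if n < 1:
            raise ConfigError(f"count for {tissue!r} must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    spectra: list[ImpedanceSpectrum] = []
    labels: list[str] = []
    for tissue in sorted(counts):
        for _ in range(counts[tissue]):
            spectra.append(sample_spectrum(templates[tissue], rng))
            labels.append(tissue)
    order = rng.permutation(len(spectra))
    return LabeledDataset(
        spectra=tuple(spectra[i] for i in order),
        labels=tuple(labels[i] for i in order),
    )


def spectrum_at_depth(
    stack: PhantomStack,
    depth_mm: float,
    templates: Mapping[str, TissueTemplate],
    seed: int | np.random.Generator = 0,
) -> tuple[ImpedanceSpectrum, str]:
    """Virtual needle measurement at a depth; returns (spectrum, true label).

    Inside a layer beyond the blend width the layer's template is sampled
    directly.  Within ``boundary_blend_mm`` of an interior interface the two
    adjacent templates are mixed log-linearly by penetration fraction (weight
    0.5 exactly at the interface).  The true label is always the layer
    geometrically containing the depth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = stack.layer_index_at(depth_mm)  # validates range
    true_label = stack.layers[idx].tissue
    template = templates[true_label]
    blend = stack.boundary_blend_mm
    if blend > 0:
        bounds = stack.boundaries_mm
        interior = bounds[1:-1]  # interfaces between layers
        if len(interior):
            j = int(np.argmin(np.abs(interior - depth_mm)))
            dist = depth_mm - interior[j]
            if abs(dist) < blend:
                upper = templates[stack.layers[j].tissue]
                lower = templates[stack.layers[j + 1].tissue]
                w = (dist + blend) / (2 * blend)  # weight of the deeper layer
                mixed = TissueTemplate(
                    tissue=true_label,
                    log_z_mean=(1 - w) * upper.log_z_mean + w * lower.log_z_mean,
                    log_z_sd=(1 - w) * upper.log_z_sd + w * lower.log_z_sd,
                    grid=template.grid,
                )
                return sample_spectrum(mixed, rng), true_label
    return sample_spectrum(template, rng), true_label


def remap_features(
    dataset: LabeledDataset, table: RemapTable
) -> tuple[np.ndarray, np.ndarray]:
    """Remap a dataset to the (n, 15) conductivity feature matrix + label indices."""
    x = np.stack([remap_spectrum(s, table).sigma_us_cm for s in dataset.spectra])
    y = encode_labels(dataset.labels)
    return x, y


def bayes_classify(
    spec: ImpedanceSpectrum,
    templates: Mapping[str, TissueTemplate],
    sd_floor: float = 0.02,
) -> str:
    """Bayes-optimal oracle under the generating model (flat class prior).

    Gaussian log-likelihood of log |Z| under each template, dispersion
    floored at ``sd_floor`` so zero-dispersion templates stay proper.
    """
    log_z = np.log(spec.z_ohm)
    best_label, best_ll = None, -np.inf
    for tissue, tpl in templates.items():
        sd = np.maximum(tpl.log_z_sd, sd_floor)
        ll = float(np.sum(-0.5 * ((log_z - tpl.log_z_mean) / sd) ** 2 - np.log(sd)))
        if ll > best_ll:
            best_label, best_ll = tissue, ll
    assert best_label is not None
    return best_label
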