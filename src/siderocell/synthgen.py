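"""Synthetic dual-reporter microscopy experiments with known ground truth.

Generates the kind of data a 24 h *Pseudomonas aeruginosa* batch-culture
sampling experiment produces: agarose-pad fields of rod-shaped cells imaged
in phase contrast plus up to three fluorescence channels (mCherry, eGFP
promoter reporters and natural pyoverdine fluorescence), together with
plate-reader growth (OD600) and bulk fluorescence (RFU) curves.

The statistical model per cell and gene is a 1- or 2-component Gaussian
mixture on log10 expression whose parameters follow a piecewise-linear
schedule over the sampling times: early time points are bimodal (a small
"on" fraction with high expression, the rest "off"), late time points are
unimodal and tighter — the funnelling pattern.  A shared per-cell metabolic
state factor ``m ~ N(0, sigma_m)`` enters every gene with loading ``beta_g``
and induces positive cross-gene correlation,

    r = beta1*beta2*sigma_m**2 /
        sqrt((beta1**2*sigma_m**2 + s1**2) * (beta2**2*sigma_m**2 + s2**2)).

Wildtype (reporter-free) cells carry only autofluorescence in the reporter
channels.  The rendered images contain the nuisances the correction chain
removes: additive pad background, an additive radial vignette field, and
Gaussian camera noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MixtureAnchor",
    "GeneSchedule",
    "PopulationParams",
    "StrainSpec",
    "GroundTruthCell",
    "OpticsParams",
    "GrowthModel",
    "FieldMeta",
    "FieldImage",
    "ExperimentConfig",
    "SyntheticExperiment",
    "sample_population",
    "render_field",
    "generate_experiment",
    "mixture_linear_mean",
    "shared_factor_correlation",
    "default_experiment_config",
    "PHASE_CHANNEL",
    "REPORTER_CHANNELS",
    "PYOVERDINE_CHANNEL",
]

PHASE_CHANNEL = "phase"
REPORTER_CHANNELS = ("mcherry", "egfp")
PYOVERDINE_CHANNEL = "pyoverdine"

LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureAnchor:
    """Mixture parameters (log10 units) at one schedule anchor time.

    ``on_fraction`` is the weight of the high-expression component;
    ``on_fraction == 0`` or ``1`` degenerates to a single Gaussian.
    """

    on_fraction: float
    mu_off: float
    mu_on: float
    sigma_off: float
    sigma_on: float

    def validate(self) -> None:
        if not 0.0 <= self.on_fraction <= 1.0:
            raise ValueError(f"on_fraction must be in [0, 1], got {self.on_fraction}")
        if self.sigma_off <= 0 or self.sigma_on <= 0:
            raise ValueError("component SDs must be > 0")


@dataclass(frozen=True)
class GeneSchedule:
    """Piecewise-linear interpolation of mixture parameters over time.

    Two anchors (an early bimodal and a late unimodal one) give the plain
    early→late funnel; more anchors allow an expression peak followed by a
    decline, as pyochelin genes show after the 9th hour.
    """

    anchors: tuple[tuple[float, MixtureAnchor], ...]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("schedule needs at least one anchor")
        times = [t for t, _ in self.anchors]
        if sorted(times) != times:
            raise ValueError("anchor times must be increasing")
        for _, a in self.anchors:
            a.validate()

    def at(self, t: float) -> MixtureAnchor:
        times = np.array([a[0] for a in self.anchors])
        if t <= times[0]:
            return self.anchors[0][1]
        if t >= times[-1]:
            return self.anchors[-1][1]
        j = int(np.searchsorted(times, t, side="right"))
        t0, a0 = self.anchors[j - 1]
        t1, a1 = self.anchors[j]
        w = (t - t0) / (t1 - t0)

        def lerp(x, y):
            return (1 - w) * x + w * y

        return MixtureAnchor(
            on_fraction=lerp(a0.on_fraction, a1.on_fraction),
            mu_off=lerp(a0.mu_off, a1.mu_off),
            mu_on=lerp(a0.mu_on, a1.mu_on),
            sigma_off=lerp(a0.sigma_off, a1.sigma_off),
            sigma_on=lerp(a0.sigma_on, a1.sigma_on),
        )


def _default_pchef_schedule() -> GeneSchedule:
    # bimodal up to 6 h (16% on), all-on by 9 h, then a moderate decline
    return GeneSchedule(
        anchors=(
            (3.0, MixtureAnchor(0.16, 2.05, 3.6, 0.18, 0.25)),
            (6.0, MixtureAnchor(0.16, 2.05, 3.6, 0.18, 0.25)),
            (9.0, MixtureAnchor(1.0, 2.05, 3.10, 0.18, 0.35)),
            (15.0, MixtureAnchor(1.0, 2.05, 2.90, 0.18, 0.22)),
            (24.0, MixtureAnchor(1.0, 2.05, 2.60, 0.18, 0.20)),
        )
    )


def _default_pvda_schedule() -> GeneSchedule:
    # gradual off-low → all-on induction, heterogeneity shrinking over time
    return GeneSchedule(
        anchors=(
            (3.0, MixtureAnchor(1.0, 2.05, 2.40, 0.18, 0.32)),
            (9.0, MixtureAnchor(1.0, 2.05, 2.90, 0.18, 0.30)),
            (15.0, MixtureAnchor(1.0, 2.05, 3.30, 0.18, 0.25)),
            (24.0, MixtureAnchor(1.0, 2.05, 3.50, 0.18, 0.22)),
        )
    )


def _default_pyoverdine_schedule() -> GeneSchedule:
    # natural pyoverdine fluorescence (made by wildtype too), rises with time
    return GeneSchedule(
        anchors=(
            (3.0, MixtureAnchor(1.0, 2.0, 2.2, 0.15, 0.30)),
            (24.0, MixtureAnchor(1.0, 2.0, 3.2, 0.15, 0.25)),
        )
    )


@dataclass
class PopulationParams:
    """Per-gene schedules, shared-factor loadings and cell geometry."""

    genes: dict[str, GeneSchedule] = field(
        default_factory=lambda: {
            "pchEF": _default_pchef_schedule(),
            "pvdA": _default_pvda_schedule(),
        }
    )
    beta: dict[str, float] = field(
        default_factory=lambda: {"pchEF": 0.5, "pvdA": 0.8, "rpsL": 1.0}
    )
    sigma_m: float = 0.15
    pyoverdine: GeneSchedule | None = field(default_factory=_default_pyoverdine_schedule)
    beta_pyoverdine: float = 0.4
    time_points_h: tuple[float, ...] = (3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0, 24.0)
    n_cells_per_field: int = 200
    autofluo_mu: dict[str, float] = field(
        default_factory=lambda: {"mcherry": 2.0, "egfp": 2.0}
    )
    autofluo_sd: float = 0.12
    # cell geometry (px)
    length_range_px: tuple[float, float] = (14.0, 22.0)
    width_range_px: tuple[float, float] = (5.0, 7.0)
    mu_shift: dict[str, float] = field(default_factory=dict)  # per-gene additive shift

    def validate(self) -> None:
        if self.sigma_m < 0 or self.autofluo_sd <= 0:
            raise ValueError("sigma_m must be >= 0 and autofluo_sd > 0")
        if self.n_cells_per_field < 1:
            raise ValueError("n_cells_per_field must be >= 1")
        for g, s in self.genes.items():
            for _, a in s.anchors:
                a.validate()


@dataclass(frozen=True)
class StrainSpec:
    """A strain and its reporter-channel → gene map (empty for wildtype)."""

    name: str
    reporters: Mapping[str, str] = field(default_factory=dict)

    @property
    def is_wildtype(self) -> bool:
        return len(self.reporters) == 0


@dataclass
class GroundTruthCell:
    """One synthetic cell: true expression per channel plus rod geometry."""

    cell_id: str
    time_h: float
    strain: str
    log_expr: dict[str, float]        # channel -> true log10 expression
    component: dict[str, str]         # channel -> "off" | "on" | "auto"
    m: float                          # metabolic-state factor
    row: float
    col: float
    orientation: float                # radians
    length_px: float
    width_px: float


def _draw_mixture(rng: np.random.Generator, anchor: MixtureAnchor, n: int):
    """Vectorized 2-component Gaussian mixture draw → (values, is_on)."""
    is_on = rng.random(n) < anchor.on_fraction
    mu = np.where(is_on, anchor.mu_on, anchor.mu_off)
    sd = np.where(is_on, anchor.sigma_on, anchor.sigma_off)
    return rng.normal(mu, sd), is_on


def _place_rods(
    rng: np.random.Generator,
    n: int,
    lengths: np.ndarray,
    widths: np.ndarray,
    orientations: np.ndarray,
    image_shape: tuple[int, int],
    margin: float,
    min_gap_px: float,
    max_tries: int = 200,
) -> np.ndarray:
    """Rejection-sample non-overlapping rod centres; error past density cap."""
    occupied = np.zeros(image_shape, dtype=bool)
    centres = np.empty((n, 2))
    h, w = image_shape
    for i in range(n):
        half = lengths[i] / 2 + widths[i] / 2 + min_gap_px
        lo_r, hi_r = margin + half, h - margin - half
        lo_c, hi_c = margin + half, w - margin - half
        if lo_r >= hi_r or lo_c >= hi_c:
            raise ValueError("image too small for requested cell geometry")
        for _ in range(max_tries):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            sl, mask = _rod_mask(r, c, orientations[i], lengths[i],
                                 widths[i] + 2 * min_gap_px, image_shape)
            if not occupied[sl][mask].any():
                occupied[sl][mask] = True
                centres[i] = (r, c)
                break
        else:
            raise ValueError(
                f"could not place cell {i + 1}/{n} without overlap; "
                "cell density exceeds the placement cap"
            )
    return centres


def _rod_mask(row, col, theta, length, width, image_shape):
    """Boolean spherocylinder mask within its bounding-box slice."""
    half = length / 2 + width / 2 + 1
    r0 = max(int(np.floor(row - half)), 0)
    r1 = min(int(np.ceil(row + half)) + 1, image_shape[0])
    c0 = max(int(np.floor(col - half)), 0)
    c1 = min(int(np.ceil(col + half)) + 1, image_shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - row
    dc = cc - col
    # coordinates along / across the rod axis
    ax = dr * np.cos(theta) + dc * np.sin(theta)
    across = -dr * np.sin(theta) + dc * np.cos(theta)
    seg_half = max(length / 2 - width / 2, 0.0)
    ax_clamped = np.clip(ax, -seg_half, seg_half)
    dist2 = (ax - ax_clamped) ** 2 + across**2
    mask = dist2 <= (width / 2) ** 2
    return (slice(r0, r1), slice(c0, c1)), mask


def sample_population(
    params: PopulationParams,
    time_h: float,
    strain: StrainSpec,
    *,
    n_cells: int | None = None,
    rng: np.random.Generator | int | None = None,
    image_shape: tuple[int, int] = (512, 512),
    margin: float = 16.0,
    min_gap_px: float = 2.0,
) -> list[GroundTruthCell]:
    """Draw one field's worth of ground-truth cells for ``strain`` at ``time_h``.

    Reporter channels of reporter strains get mixture draws plus the shared
    metabolic-state contribution ``beta_g * m``; the same channels of the
    wildtype get an autofluorescence draw; the pyoverdine channel (if
    configured) is drawn for every strain.  Deterministic under a fixed rng.
    """
    params.validate()
    if time_h not in params.time_points_h:
        raise ValueError(f"time {time_h} h not in configured time points {params.time_points_h}")
    for ch, gene in strain.reporters.items():
        if gene not in params.genes:
            raise ValueError(f"strain {strain.name!r} reports unknown gene {gene!r}")
        if ch not in params.autofluo_mu:
            raise ValueError(f"strain {strain.name!r} uses unknown channel {ch!r}")
    rng = np.random.default_rng(rng)
    n = params.n_cells_per_field if n_cells is None else int(n_cells)

    lengths = rng.uniform(*params.length_range_px, size=n)
    widths = rng.uniform(*params.width_range_px, size=n)
    widths = np.minimum(widths, lengths - 1e-6)  # keep length > width
    orientations = rng.uniform(0, np.pi, size=n)
    centres = _place_rods(rng, n, lengths, widths, orientations,
                          image_shape, margin, min_gap_px)
    m = rng.normal(0.0, params.sigma_m, size=n)

    expr: dict[str, np.ndarray] = {}
    comp: dict[str, np.ndarray] = {}
    for ch in params.autofluo_mu:  # reporter-capable channels
        if ch in strain.reporters:
            gene = strain.reporters[ch]
            anchor = params.genes[gene].at(time_h)
            shift = params.mu_shift.get(gene, 0.0)
            if shift:
                anchor = replace(anchor, mu_off=anchor.mu_off + shift,
                                 mu_on=anchor.mu_on + shift)
            vals, is_on = _draw_mixture(rng, anchor, n)
            expr[ch] = vals + params.beta.get(gene, 0.0) * m
            comp[ch] = np.where(is_on, "on", "off")
        else:
            expr[ch] = rng.normal(params.autofluo_mu[ch], params.autofluo_sd, size=n)
            comp[ch] = np.full(n, "auto")
    if params.pyoverdine is not None:
        anchor = params.pyoverdine.at(time_h)
        vals, is_on = _draw_mixture(rng, anchor, n)
        expr[PYOVERDINE_CHANNEL] = vals + params.beta_pyoverdine * m
        comp[PYOVERDINE_CHANNEL] = np.where(is_on, "on", "off")

    cells = []
    for i in range(n):
        cells.append(
            GroundTruthCell(
                cell_id=f"c{i:04d}",
                time_h=time_h,
                strain=strain.name,
                log_expr={ch: float(v[i]) for ch, v in expr.items()},
                component={ch: str(v[i]) for ch, v in comp.items()},
                m=float(m[i]),
                row=float(centres[i, 0]),
                col=float(centres[i, 1]),
                orientation=float(orientations[i]),
                length_px=float(lengths[i]),
                width_px=float(widths[i]),
            )
        )
    return cells


def cells_to_frame(cells: Sequence[GroundTruthCell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        row = {
            "cell_id": c.cell_id,
            "time_h": c.time_h,
            "strain": c.strain,
            "m": c.m,
            "row": c.row,
            "col": c.col,
            "orientation": c.orientation,
            "length_px": c.length_px,
            "width_px": c.width_px,
        }
        for ch, v in c.log_expr.items():
            row[f"expr_{ch}"] = v
            row[f"comp_{ch}"] = c.component[ch]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optics & rendering
# ---------------------------------------------------------------------------

@dataclass
class OpticsParams:
    """Camera/optics model: additive vignette, pad background, noise, PSF."""

    image_shape_px: tuple[int, int] = (512, 512)
    vignette_amplitude: float = 8.0
    vignette_profile: tuple[float, ...] = (1.0, 0.0, -0.8)  # poly in rho = r/r_max
    pad_background_mu: float = 100.0
    pad_background_sd: float = 2.0
    read_noise_sd: float = 2.0
    photon_scale: float = 100.0  # grey units per linear expression unit
    psf_sigma_px: float = 0.6
    phase_background: float = 8000.0
    phase_cell_depth: float = 3500.0

    def validate(self) -> None:
        if self.pad_background_mu < 0:
            raise ValueError("pad_background_mu must be >= 0")
        rho = np.linspace(0, 1, 101)
        if np.any(self.vignette_field_1d(rho) < 0):
            raise ValueError("vignette field must be >= 0 everywhere")

    def vignette_field_1d(self, rho: np.ndarray) -> np.ndarray:
        return self.vignette_amplitude * np.polyval(self.vignette_profile[::-1], rho)

    def vignette_field(self) -> np.ndarray:
        key = (self.image_shape_px, self.vignette_amplitude, self.vignette_profile)
        cached = getattr(self, "_vignette_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1]
        h, w = self.image_shape_px
        rr, cc = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2, (w - 1) / 2
        rho = np.hypot(rr - cy, cc - cx) / np.hypot(cy, cx)
        field_arr = self.vignette_field_1d(rho)
        object.__setattr__(self, "_vignette_cache", (key, field_arr))
        return field_arr

    def noiseless(self) -> "OpticsParams":
        return replace(self, pad_background_sd=0.0, read_noise_sd=0.0)


@dataclass(frozen=True)
class FieldMeta:
    condition: str
    time_h: float
    strain: str
    repeat: int
    field_id: int
    kind: str = "cells"  # "cells" | "blank"

    @property
    def pad_key(self) -> tuple:
        # one agarose pad per (condition, time, strain, repeat)
        return (self.condition, self.time_h, self.strain, self.repeat)


@dataclass
class FieldImage:
    """One imaged position: float64 channel stack plus acquisition metadata."""

    channels: dict[str, np.ndarray]
    meta: FieldMeta


def render_field(
    cells: Sequence[GroundTruthCell],
    optics: OpticsParams,
    *,
    rng: np.random.Generator | int | None = None,
    meta: FieldMeta | None = None,
    fluor_channels: Sequence[str] | None = None,
) -> FieldImage:
    """Render one field: phase contrast plus the fluorescence channels.

    Each cell contributes a uniform-interior rod whose *total* flux in
    channel ``ch`` is ``photon_scale * 10**log_expr[ch]``; the canvas is
    blurred with a Gaussian PSF, then the additive vignette field, pad
    background and Gaussian camera noise are added.  Phase contrast renders
    dark rods on a bright background.
    """
    optics.validate()
    rng = np.random.default_rng(rng)
    shape = optics.image_shape_px
    if fluor_channels is None:
        chans: list[str] = sorted({ch for c in cells for ch in c.log_expr})
        if not chans:
            chans = [*REPORTER_CHANNELS, PYOVERDINE_CHANNEL]
    else:
        chans = list(fluor_channels)

    canvases = {ch: np.zeros(shape) for ch in chans}
    phase_canvas = np.zeros(shape)
    for c in cells:
        half = c.length_px / 2 + c.width_px / 2
        if not (half <= c.row <= shape[0] - 1 - half and half <= c.col <= shape[1] - 1 - half):
            raise ValueError(f"cell {c.cell_id} does not fit within image bounds")
        sl, mask = _rod_mask(c.row, c.col, c.orientation, c.length_px, c.width_px, shape)
        area = mask.sum()
        for ch in chans:
            if ch in c.log_expr:
                canvases[ch][sl][mask] += optics.photon_scale * 10.0 ** c.log_expr[ch] / area
        phase_canvas[sl][mask] = 1.0

    vignette = optics.vignette_field()
    out: dict[str, np.ndarray] = {}
    for ch in chans:
        canvas = canvases[ch]
        if cells and canvas.any():
            canvas = ndimage.gaussian_filter(canvas, optics.psf_sigma_px)
        img = canvas + vignette + optics.pad_background_mu
        if optics.pad_background_sd > 0:
            img = img + rng.normal(0, optics.pad_background_sd, shape)
        if optics.read_noise_sd > 0:
            img = img + rng.normal(0, optics.read_noise_sd, shape)
        out[ch] = img
    if cells:
        phase_canvas = ndimage.gaussian_filter(phase_canvas, optics.psf_sigma_px)
    phase = optics.phase_background - optics.phase_cell_depth * phase_canvas
    if optics.read_noise_sd > 0:
        phase = phase + rng.normal(0, optics.read_noise_sd, shape)
    out[PHASE_CHANNEL] = phase
    if meta is None:
        meta = FieldMeta("unspecified", float(cells[0].time_h) if cells else 0.0,
                         cells[0].strain if cells else "none", 0, 0,
                         "cells" if cells else "blank")
    return FieldImage(channels=out, meta=meta)


# ---------------------------------------------------------------------------
# closed forms used by tests and the plate-reader layer
# ---------------------------------------------------------------------------

def mixture_linear_mean(anchor: MixtureAnchor, beta: float = 0.0, sigma_m: float = 0.0) -> float:
    """E[10^X] for the mixture-plus-shared-factor log10 expression model."""
    shared = np.exp(0.5 * (beta * sigma_m * LN10) ** 2)

    def comp(mu, sd):
        return 10.0**mu * np.exp(0.5 * (sd * LN10) ** 2)

    w = anchor.on_fraction
    return float(((1 - w) * comp(anchor.mu_off, anchor.sigma_off)
                  + w * comp(anchor.mu_on, anchor.sigma_on)) * shared)


def shared_factor_correlation(beta1: float, beta2: float, sigma_m: float,
                              s1: float, s2: float) -> float:
    """Closed-form Pearson r induced by the shared metabolic-state factor."""
    v = sigma_m**2
    num = beta1 * beta2 * v
    den = np.sqrt((beta1**2 * v + s1**2) * (beta2**2 * v + s2**2))
    return float(num / den)


# ---------------------------------------------------------------------------
# experiment-level generation
# ---------------------------------------------------------------------------

@dataclass
class GrowthModel:
    """Lagged logistic OD600 growth for one condition."""

    od0: float = 1e-4       # inoculum, OD600 (paper-style starting density)
    K: float = 1.2          # carrying capacity
    mu: float = 0.55        # max specific growth rate, 1/h
    lag_h: float = 2.0

    def od(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        te = np.maximum(t - self.lag_h, 0.0)
        if self.mu == 0:
            return np.full_like(t, self.od0)
        return self.K / (1.0 + (self.K / self.od0 - 1.0) * np.exp(-self.mu * te))


@dataclass
class ExperimentConfig:
    """Full sampling design: conditions × time points × strains × repeats."""

    conditions: tuple[str, ...] = ("iron_replete", "bipyridyl_100", "bipyridyl_300")
    strains: tuple[StrainSpec, ...] = (
        StrainSpec("PAO1_wt"),
        StrainSpec("double_reporter", {"mcherry": "pvdA", "egfp": "pchEF"}),
    )
    repeats: int = 2
    n_cell_fields: int = 6
    n_blank_fields: int = 4
    population: PopulationParams = field(default_factory=PopulationParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    growth: dict[str, GrowthModel] = field(default_factory=dict)
    # per-condition additive shift of gene means (iron-replete: repressed)
    condition_mu_shift: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "iron_replete": {"pvdA": -0.25, "pchEF": -0.15},
            "bipyridyl_100": {},
            "bipyridyl_300": {"pvdA": 0.2, "pchEF": -0.1},
        }
    )
    # per-repeat systematic offset of log expression (batch effect the fuse
    # step removes); drawn N(0, repeat_offset_sd) per (repeat, channel)
    repeat_offset_sd: float = 0.15
    plate_dt_h: float = 0.25
    rfu_scale: float = 1.0e-3
    seed: int = 0

    def validate(self) -> None:
        n_wt = sum(1 for s in self.strains if s.is_wildtype)
        if n_wt != 1:
            raise ValueError(
                "config must contain exactly one wildtype (reporter-free) strain; "
                f"found {n_wt} — the autofluorescence correction step requires it"
            )
        names = [s.name for s in self.strains]
        if len(set(names)) != len(names):
            raise ValueError("strain names must be unique")
        if self.repeats < 1 or self.n_cell_fields < 1 or self.n_blank_fields < 1:
            raise ValueError("repeats and field counts must be >= 1")
        if self.n_blank_fields < 4:
            warnings.warn("fewer than 4 blank fields per pad", stacklevel=2)
        self.population.validate()
        self.optics.validate()

    @property
    def wildtype(self) -> StrainSpec:
        return next(s for s in self.strains if s.is_wildtype)

    def growth_model(self, condition: str) -> GrowthModel:
        if condition in self.growth:
            return self.growth[condition]
        # default: iron limitation lengthens lag / lowers capacity
        i = self.conditions.index(condition) if condition in self.conditions else 0
        return GrowthModel(K=1.2 - 0.15 * i, mu=0.55 - 0.04 * i, lag_h=2.0 + 0.8 * i)


def _field_seed(cfg: ExperimentConfig, meta: FieldMeta) -> np.random.SeedSequence:
    key = (
        cfg.seed,
        cfg.conditions.index(meta.condition),
        int(meta.time_h * 10),
        [s.name for s in cfg.strains].index(meta.strain),
        meta.repeat,
        meta.field_id,
        0 if meta.kind == "cells" else 1,
    )
    return np.random.SeedSequence(key)


class SyntheticExperiment:
    """Generated experiment: lazy field images, eager truth and plate tables.

    Field images are re-derived deterministically from the config seed tree,
    so iterating fields never needs the whole image set in memory at once.
    """

    def __init__(self, config: ExperimentConfig):
        config.validate()
        self.config = config
        self._truth: pd.DataFrame | None = None
        self._plate: pd.DataFrame | None = None

    # -- enumeration -------------------------------------------------------

    def field_metas(self) -> Iterator[FieldMeta]:
        cfg = self.config
        for cond in cfg.conditions:
            for t in cfg.population.time_points_h:
                for s in cfg.strains:
                    for rep in range(1, cfg.repeats + 1):
                        for f in range(1, cfg.n_cell_fields + 1):
                            yield FieldMeta(cond, t, s.name, rep, f, "cells")
                        for f in range(1, cfg.n_blank_fields + 1):
                            yield FieldMeta(cond, t, s.name, rep, f, "blank")

    def _strain(self, name: str) -> StrainSpec:
        return next(s for s in self.config.strains if s.name == name)

    def _repeat_offset(self, repeat: int, channel: str) -> float:
        cfg = self.config
        if cfg.repeat_offset_sd == 0:
            return 0.0
        idx = [*REPORTER_CHANNELS, PYOVERDINE_CHANNEL].index(channel)
        ss = np.random.SeedSequence((cfg.seed, 90001, repeat, idx))
        return float(np.random.default_rng(ss).normal(0, cfg.repeat_offset_sd))

    def cells_for(self, meta: FieldMeta) -> list[GroundTruthCell]:
        cfg = self.config
        if meta.kind != "cells":
            return []
        pop = cfg.population
        shift = dict(pop.mu_shift)
        for g, v in cfg.condition_mu_shift.get(meta.condition, {}).items():
            shift[g] = shift.get(g, 0.0) + v
        pop_c = replace(pop, mu_shift=shift) if shift != pop.mu_shift else pop
        rng = np.random.default_rng(_field_seed(cfg, meta))
        cells = sample_population(
            pop_c, meta.time_h, self._strain(meta.strain),
            rng=rng, image_shape=cfg.optics.image_shape_px,
        )
        # batch effect: per-repeat multiplicative offset (additive in log)
        for c in cells:
            for ch in c.log_expr:
                c.log_expr[ch] += self._repeat_offset(meta.repeat, ch)
        return cells

    def render(self, meta: FieldMeta, cells: Sequence[GroundTruthCell] | None = None) -> FieldImage:
        cfg = self.config
        if cells is None:
            cells = self.cells_for(meta)
        rng = np.random.default_rng(_field_seed(cfg, meta).spawn(1)[0])
        chans = list(cfg.population.autofluo_mu)
        if cfg.population.pyoverdine is not None:
            chans.append(PYOVERDINE_CHANNEL)
        return render_field(cells, cfg.optics, rng=rng, meta=meta, fluor_channels=chans)

    def iter_fields(self, *, render: bool = True):
        """Yield ``(meta, cells, field_image_or_None)`` for every field."""
        for meta in self.field_metas():
            cells = self.cells_for(meta)
            yield meta, cells, (self.render(meta, cells) if render else None)

    # -- eager tables ------------------------------------------------------

    @property
    def ground_truth(self) -> pd.DataFrame:
        if self._truth is None:
            frames = []
            for meta in self.field_metas():
                if meta.kind != "cells":
                    continue
                df = cells_to_frame(self.cells_for(meta))
                df.insert(0, "condition", meta.condition)
                df.insert(3, "repeat", meta.repeat)
                df.insert(4, "field", meta.field_id)
                frames.append(df)
            self._truth = pd.concat(frames, ignore_index=True)
        return self._truth

    @property
    def plate_reader(self) -> pd.DataFrame:
        if self._plate is None:
            self._plate = self._make_plate_reader()
        return self._plate

    def _make_plate_reader(self) -> pd.DataFrame:
        cfg = self.config
        pop = cfg.population
        t = np.arange(0.0, 24.0 + 1e-9, cfg.plate_dt_h)
        rows = []
        for cond in cfg.conditions:
            gm = cfg.growth_model(cond)
            od = gm.od(t)
            for s in cfg.strains:
                for rep in range(1, cfg.repeats + 1):
                    rng = np.random.default_rng(
                        np.random.SeedSequence((cfg.seed, 70001,
                                                cfg.conditions.index(cond),
                                                [x.name for x in cfg.strains].index(s.name),
                                                rep)))
                    noise = rng.normal(1.0, 0.01, size=t.size)
                    for ti, (tt, oo) in enumerate(zip(t, od)):
                        rows.append((cond, s.name, rep, tt, "od600", float(oo * noise[ti])))
                    for ch in pop.autofluo_mu:
                        vals = np.empty_like(t)
                        for i, tt in enumerate(t):
                            tq = float(np.clip(tt, pop.time_points_h[0], pop.time_points_h[-1]))
                            if ch in s.reporters:
                                gene = s.reporters[ch]
                                anchor = pop.genes[gene].at(tq)
                                shift = cfg.condition_mu_shift.get(cond, {}).get(gene, 0.0)
                                anchor = replace(anchor, mu_off=anchor.mu_off + shift,
                                                 mu_on=anchor.mu_on + shift)
                                mlin = mixture_linear_mean(anchor, pop.beta.get(gene, 0.0), pop.sigma_m)
                            else:
                                mlin = 10.0 ** pop.autofluo_mu[ch] * np.exp(
                                    0.5 * (pop.autofluo_sd * LN10) ** 2)
                            vals[i] = cfg.rfu_scale * od[i] * mlin
                        vals = vals * rng.normal(1.0, 0.01, size=t.size)
                        for tt, vv in zip(t, vals):
                            rows.append((cond, s.name, rep, float(tt), ch, float(vv)))
        return pd.DataFrame(rows, columns=["condition", "strain", "repeat",
                                           "time_h", "channel", "value"])

    # -- disk output -------------------------------------------------------

    def write(self, out_dir) -> None:
        """Write TIFF tree + ground truth / plate-reader CSVs + config YAML."""
        import tifffile
        import yaml
        from pathlib import Path

        out = Path(out_dir)
        for meta, _cells, img in self.iter_fields(render=True):
            d = out / meta.condition / f"{meta.time_h:g}" / meta.strain / f"r{meta.repeat}"
            d.mkdir(parents=True, exist_ok=True)
            stem = "field" if meta.kind == "cells" else "blank"
            for ch, arr in img.channels.items():
                u16 = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
                tifffile.imwrite(d / f"{stem}{meta.field_id}_{ch}.tif", u16)
        self.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        self.plate_reader.to_csv(out / "plate_reader.csv", index=False)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(_config_to_dict(self.config), fh, sort_keys=False)


def _config_to_dict(cfg: ExperimentConfig) -> dict:
    return {
        "conditions": list(cfg.conditions),
        "strains": [{"name": s.name, "reporters": dict(s.reporters)} for s in cfg.strains],
        "repeats": cfg.repeats,
        "n_cell_fields": cfg.n_cell_fields,
        "n_blank_fields": cfg.n_blank_fields,
        "seed": cfg.seed,
        "n_cells_per_field": cfg.population.n_cells_per_field,
        "image_shape_px": list(cfg.optics.image_shape_px),
    }


def generate_experiment(config: ExperimentConfig) -> SyntheticExperiment:
    """Validate the design and return the (lazily rendered) experiment."""
    return SyntheticExperiment(config)


def default_experiment_config(**overrides) -> ExperimentConfig:
    """The default study design: 3 media × 8 time points × 2 strains × 2 repeats."""
    cfg = ExperimentConfig(**overrides)
    cfg.validate()
    return cfg
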