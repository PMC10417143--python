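"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the data classes the pipeline consumes:

* :func:`make_stack` — 3-channel z-stacks in which the marker either spreads
  as a web of fibrous filaments through the stroma or stays confined inside
  tumor nests, with exact voxel-level ground truth;
* :func:`make_layer_profiles` — paired per-layer relative-intensity series
  with a controllable fraction of layers above a dichotomization cutoff;
* :func:`make_survival_table` — survival times with a hazard step at a known
  expression cutoff plus age/sex/smoking/alcohol covariates;
* :func:`make_de_tables` — two log2 fold-change tables with an exact planted
  number of concordant (up in one contrast, down in the other) genes.

Every generator is a pure function of its arguments: identical inputs,
including the seed, yield identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .quant import DEFAULT_Z_STEP, ImageStack, LayerProfile

PATTERNS = ("stromal-web", "nest-confined")

# Fixed nominal intensities for noise-free voxels of each channel (16-bit range).
MARKER_LEVEL = 180
MEMBRANE_LEVEL = 120
NUCLEI_LEVEL = 220


@dataclass(frozen=True)
class StackSpec:
    """Parameters of one synthetic z-stack.

    ``marker_density`` is the fraction of the marker's compartment (nest
    voxels for 'nest-confined', stroma voxels for 'stromal-web') that carries
    marker signal; with equal densities the web pattern therefore yields much
    higher per-layer relative intensity simply because the stroma is the
    larger compartment — the contrast the two observed tissue phenotypes show.
    """

    n_layers: int = 60
    height: int = 64
    width: int = 64
    z_step: float = DEFAULT_Z_STEP
    pattern: str = "nest-confined"
    marker_density: float = 0.1
    nest_count: int = 4
    nest_radius: float = 12.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ConfigurationError(
                f"pattern must be one of {PATTERNS}, got {self.pattern!r}"
            )
        if self.n_layers < 1:
            raise ConfigurationError("n_layers must be >= 1")
        if self.height < 16 or self.width < 16:
            raise ConfigurationError("height and width must be >= 16")
        if self.z_step <= 0:
            raise ConfigurationError("z_step must be positive")
        if not 0 <= self.marker_density <= 1:
            raise ConfigurationError("marker_density must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.nest_count < 0 or self.nest_radius <= 0:
            raise ConfigurationError("nest geometry must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Voxel-level truth for one synthetic stack.

    ``expected_profile[z]`` is the true relative intensity of layer ``z``:
    marker voxels divided by membrane voxels in that layer (the membrane
    covers the whole tissue, so the denominator is height*width).
    """

    nest_mask: np.ndarray
    marker_mask: np.ndarray
    expected_profile: np.ndarray = field(compare=False)


def _ball_mask(shape: tuple[int, int, int], center: np.ndarray, radius: float) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return d2 <= radius**2


def _draw_nests(rng: np.random.Generator, spec: StackSpec) -> np.ndarray:
    """Random spheres of ~nest_radius; the complement is stroma."""
    shape = (spec.n_layers, spec.height, spec.width)
    nest = np.zeros(shape, dtype=bool)
    for _ in range(spec.nest_count):
        center = rng.uniform(0, 1, 3) * np.array(shape)
        radius = spec.nest_radius * rng.uniform(0.8, 1.2)
        nest |= _ball_mask(shape, center, radius)
    return nest


def _draw_web(rng: np.random.Generator, spec: StackSpec, stroma: np.ndarray) -> np.ndarray:
    """Marker as random 3-D polyline filaments dilated to ~1 voxel, in stroma.

    Filaments are added until the stromal marker fraction reaches
    ``marker_density`` (or an attempt cap, so degenerate geometries cannot
    loop forever); the realized mask is the exact ground truth.
    """
    shape = np.array(stroma.shape)
    marker = np.zeros(stroma.shape, dtype=bool)
    target = spec.marker_density * stroma.sum()
    stroma_idx = np.argwhere(stroma)
    if target <= 0 or stroma_idx.size == 0:
        return marker
    offsets = np.array(
        [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    )
    attempts = 0
    while marker.sum() < target and attempts < 500:
        attempts += 1
        pos = stroma_idx[rng.integers(len(stroma_idx))].astype(float)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        n_steps = int(rng.integers(30, 80))
        pts = np.empty((n_steps, 3))
        for i in range(n_steps):
            pts[i] = pos
            direction += rng.normal(0, 0.35, 3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction
        vox = np.rint(pts).astype(int)[:, None, :] + offsets[None, :, :]
        vox = vox.reshape(-1, 3)
        keep = np.all((vox >= 0) & (vox < shape), axis=1)
        vox = vox[keep]
        fil = np.zeros(stroma.shape, dtype=bool)
        fil[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        marker |= fil & stroma
    return marker


def make_stack(spec: StackSpec) -> tuple[ImageStack, GroundTruth]:
    """Generate one 3-channel stack and its voxel-level ground truth.

    The membrane channel covers the whole tissue (every voxel), nuclei are
    small blobs scattered through it, and the marker follows ``spec.pattern``:
    a random subset of nest voxels at ``marker_density`` ('nest-confined') or
    stroma-restricted filament webs at that density ('stromal-web').  Additive
    Gaussian noise of sd ``noise_sd`` is clamped at zero and quantized to
    16-bit output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_layers, spec.height, spec.width)

    nest = _draw_nests(rng, spec)
    stroma = ~nest
    if spec.pattern == "nest-confined":
        marker = nest & (rng.random(shape) < spec.marker_density)
    else:
        marker = _draw_web(rng, spec, stroma)

    membrane = np.ones(shape, dtype=bool)
    nuclei_seed = rng.random(shape) < 0.01
    nuclei = np.zeros(shape, dtype=bool)
    for dz, dy, dx in ((0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0)):
        nuclei |= np.roll(np.roll(np.roll(nuclei_seed, dz, 0), dy, 1), dx, 2)

    voxels = np.stack(
        [
            marker * MARKER_LEVEL,
            membrane * MEMBRANE_LEVEL,
            nuclei * NUCLEI_LEVEL,
        ]
    ).astype(float)
    if spec.noise_sd > 0:
        voxels += rng.normal(0.0, spec.noise_sd, voxels.shape)
    voxels = np.clip(np.rint(voxels), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    per_layer_marker = marker.sum(axis=(1, 2))
    expected = per_layer_marker / float(spec.height * spec.width)
    truth = GroundTruth(nest_mask=nest, marker_mask=marker, expected_profile=expected)
    return ImageStack(voxels, z_step=spec.z_step), truth


def make_layer_profiles(
    n_layers: int,
    frac_above: tuple[float, float] = (0.5, 0.5),
    cutoff: float = 0.05,
    seed: int = 0,
) -> tuple[LayerProfile, LayerProfile]:
    """Draw two subjects' per-layer relative-intensity series.

    Each layer is independently above the cutoff with the subject's
    ``frac_above`` probability; above-cutoff values are cutoff*(1+Exp(1)),
    below-cutoff values uniform on [0, cutoff).  All values are nonnegative.
    """
    if n_layers < 1:
        raise ConfigurationError("n_layers must be >= 1")
    for f in frac_above:
        if not 0 <= f <= 1:
            raise ConfigurationError("frac_above entries must be in [0, 1]")
    rng = np.random.default_rng(seed)
    profiles = []
    for f in frac_above:
        above = rng.random(n_layers) < f
        high = cutoff * (1.0 + rng.exponential(1.0, n_layers))
        low = rng.uniform(0.0, cutoff, n_layers)
        r = np.where(above, high, low)
        profiles.append(LayerProfile(r=r, defined=np.ones(n_layers, dtype=bool)))
    return profiles[0], profiles[1]


#: Default per-covariate log-hazards (age per year above 58; binaries 0/1).
DEFAULT_COVARIATE_EFFECTS = {"age": 0.02, "sex": 0.3, "smoking": 0.3, "alcohol": 0.2}

#: Offsets (in expression units) of the discrete expression levels around the
#: planted cutoff.  Levels straddle the cutoff symmetrically so it sits in the
#: middle of a genuine inter-subject gap; see the methods note.
EXPRESSION_LEVEL_OFFSETS = (-7.0, -5.0, -3.0, -1.0, 1.0, 3.0, 5.0, 7.0)


def make_survival_table(
    n: int = 400,
    true_cutoff: float = 25.0,
    hazard_ratio: float = 6.0,
    censor_rate: float = 0.2,
    covariate_effects: dict[str, float] | None = None,
    seed: int = 0,
    baseline_hazard: float = 0.05,
    expression_levels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate a survival cohort with a hazard step at a known cutoff.

    Survival times are exponential with subject hazard
    ``baseline_hazard * exp(lp) * hazard_ratio**(expression > true_cutoff)``
    where ``lp`` applies the covariate log-hazards (age centered at 58 years).
    Censoring is an independent exponential whose rate is solved so the
    expected censored fraction equals ``censor_rate``.  Expression is drawn
    uniformly from a discrete level grid straddling the cutoff.

    Columns: ``expression,time,event,age,sex,smoking,alcohol``.
    """
    if n < 20:
        raise ConfigurationError("n must be >= 20")
    if hazard_ratio <= 0:
        raise ConfigurationError("hazard_ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ConfigurationError("censor_rate must be in [0, 1)")
    effects = dict(DEFAULT_COVARIATE_EFFECTS if covariate_effects is None else covariate_effects)
    if expression_levels is None:
        expression_levels = true_cutoff + np.asarray(EXPRESSION_LEVEL_OFFSETS)
    rng = np.random.default_rng(seed)

    expression = rng.choice(np.asarray(expression_levels, dtype=float), size=n)
    age = rng.normal(58.0, 8.0, n)
    sex = (rng.random(n) < 0.8).astype(int)
    smoking = (rng.random(n) < 0.5).astype(int)
    alcohol = (rng.random(n) < 0.5).astype(int)

    lp = (
        effects.get("age", 0.0) * (age - 58.0)
        + effects.get("sex", 0.0) * sex
        + effects.get("smoking", 0.0) * smoking
        + effects.get("alcohol", 0.0) * alcohol
    )
    hazard = baseline_hazard * np.exp(lp) * np.where(
        expression > true_cutoff, hazard_ratio, 1.0
    )
    t_event = rng.exponential(1.0 / hazard)

    if censor_rate == 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        # With exponential censoring at rate mu, P(censored | hazard h) = mu/(mu+h);
        # bisect mu so the cohort-average censored fraction matches censor_rate.
        lo, hi = 1e-12, 1e6
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if np.mean(mid / (mid + hazard)) < censor_rate:
                lo = mid
            else:
                hi = mid
        t_cens = rng.exponential(1.0 / np.sqrt(lo * hi), n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)

    return pd.DataFrame(
        {
            "expression": expression,
            "time": time,
            "event": event,
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "alcohol": alcohol,
        }
    )


def make_de_tables(
    n_genes: int,
    n_concordant: int,
    lfc_threshold: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two log2 fold-change tables with an exact planted concordant set.

    Exactly ``n_concordant`` genes satisfy lfc > threshold in the first
    (overexpression) table AND lfc < -threshold in the second (knockdown)
    table; every other gene violates at least one condition.
    """
    if not 0 <= n_concordant <= n_genes:
        raise ConfigurationError("need 0 <= n_concordant <= n_genes")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    concordant = np.zeros(n_genes, dtype=bool)
    concordant[rng.permutation(n_genes)[:n_concordant]] = True

    up = np.where(
        concordant,
        lfc_threshold + rng.exponential(1.0, n_genes) + 1e-9,
        rng.normal(0.0, 2.0, n_genes),
    )
    down = np.where(
        concordant,
        -(lfc_threshold + rng.exponential(1.0, n_genes) + 1e-9),
        rng.normal(0.0, 2.0, n_genes),
    )
    # Force non-concordant genes to fail at least one condition: squeeze one
    # randomly chosen side strictly inside [-threshold, threshold].
    fail_up = rng.random(n_genes) < 0.5
    inside = rng.uniform(-lfc_threshold, lfc_threshold, n_genes)
    bad = ~concordant
    up[bad & fail_up] = inside[bad & fail_up]
    down[bad & ~fail_up] = np.abs(inside[bad & ~fail_up])  # >= -threshold

    up_table = pd.DataFrame({"gene": genes, "log2fc": up})
    down_table = pd.DataFrame({"gene": genes, "log2fc": down})
    return up_table, down_table
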