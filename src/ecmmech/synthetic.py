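"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline (mechanics, intensity, cell
quantification, statistics) is tested against data produced here, because the
generators return the true parameters next to each artifact.

The force-curve generator uses the Hertz sphere contact model as a *forward*
model: for a rigid sphere of radius ``R`` indenting an elastic half-space by
``delta``,

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2).

On a soft cantilever the measured piezo travel ``z - z0`` splits between
sample indentation and cantilever bending, ``delta = (z - z0) - F/k``, so the
force at each piezo position is the root of an implicit equation; it is
solved per point by bracketed root finding (Brent) on delta in [0, z - z0].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk, line as draw_line

from .types import CurveBatch, CurveGroundTruth, CurveRecord, ForceCurve


def hertz_force(E: float, R: float, nu: float, delta) -> np.ndarray:
    """Closed-form Hertz sphere force at indentation depth delta (m) -> N."""
    delta = np.asarray(delta, dtype=float)
    return (4.0 / 3.0) * (E / (1.0 - nu**2)) * np.sqrt(R) * np.clip(delta, 0.0, None) ** 1.5


# ---------------------------------------------------------------------------
# Force curves
# ---------------------------------------------------------------------------

@dataclass
class CurveGenSpec:
    """Parameters of one synthetic indentation curve.

    Defaults reproduce the probe used for the lung scaffolds: a 0.03 N/m
    cantilever carrying a 5 µm silica bead (R = 2.5 µm), incompressible
    sample (nu = 0.5), a ~3 µm ramp reaching about 1 µm of indentation, and
    5 pN additive deflection-force noise.
    """

    E_true: float = 470.0            # Pa
    R: float = 2.5e-6                # m
    k: float = 0.03                  # N/m
    nu: float = 0.5
    z0_true: float = 2.0e-6          # m
    z_range: tuple[float, float] = (0.0, 3.1e-6)   # m
    n_samples_per_segment: int = 400
    noise_sd: float = 5e-12          # N
    baseline_slope: float = 0.0      # N/m
    adhesion_depth: float = 1.0e-9   # N
    adhesion_width: float = 1.5e-7   # m
    hysteresis_factor: float = 0.1   # dimensionless, [0, 1)
    seed: int = 0

    def validate(self) -> None:
        if self.E_true <= 0:
            raise ValueError("E_true must be > 0")
        if self.R <= 0 or self.k <= 0:
            raise ValueError("R and k must be > 0")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("nu must be in [0, 0.5]")
        lo, hi = self.z_range
        if not lo < self.z0_true < hi:
            raise ValueError("z_range must span z0_true")
        if self.n_samples_per_segment < 50:
            raise ValueError("n_samples_per_segment must be >= 50")
        if min(self.noise_sd, self.adhesion_depth, self.adhesion_width) < 0:
            raise ValueError("noise/adhesion parameters must be >= 0")
        if not 0.0 <= self.hysteresis_factor < 1.0:
            raise ValueError("hysteresis_factor must be in [0, 1)")


def _solve_contact_force(u: np.ndarray, A: float, k: float) -> np.ndarray:
    """Solve F = A*delta^1.5 with delta = u - F/k for each piezo overshoot u >= 0.

    Solved in delta: g(delta) = A*delta^1.5 + k*delta - k*u, monotone on
    [0, u], bracketed root via Brent to ~machine precision.
    """
    F = np.zeros_like(u)
    for i, ui in enumerate(u):
        if ui <= 0.0:
            continue

        def g(d: float, ui: float = ui) -> float:
            return A * d**1.5 + k * d - k * ui

        try:
            d = brentq(g, 0.0, ui, xtol=1e-18, rtol=8.9e-16, maxiter=200)
        except (ValueError, RuntimeError) as exc:  # pragma: no cover - malformed spec
            raise RuntimeError(f"contact-force solve failed at u={ui!r}: {exc}") from exc
        F[i] = A * d**1.5
    return F


def _render_curve(spec: CurveGenSpec, z0: float, rng: np.random.Generator,
                  curve_id: str, seed_key: tuple[int, ...]) -> tuple[ForceCurve, CurveGroundTruth]:
    A = (4.0 / 3.0) * (spec.E_true / (1.0 - spec.nu**2)) * np.sqrt(spec.R)
    z = np.linspace(spec.z_range[0], spec.z_range[1], spec.n_samples_per_segment)
    F_contact = _solve_contact_force(z - z0, A, spec.k)
    baseline = spec.baseline_slope * (z - z[0])

    F_app = F_contact + baseline
    if spec.noise_sd > 0:
        F_app = F_app + rng.normal(0.0, spec.noise_sd, z.size)

    # Withdrawal retraces the same piezo positions in reverse; contact forces
    # are reduced by the hysteresis factor and a Gaussian pull-off well is
    # centred on the sampled z nearest to z0 - 2*width (just outside contact,
    # so the sampled minimum equals -adhesion_depth exactly when noiseless).
    z_ret = z[::-1]
    F_ret_contact = (1.0 - spec.hysteresis_factor) * F_contact[::-1]
    adhesion_center = z0
    well = np.zeros_like(z_ret)
    if spec.adhesion_depth > 0:
        target = z0 - 2.0 * spec.adhesion_width
        adhesion_center = z[np.argmin(np.abs(z - target))]
        if spec.adhesion_width > 0:
            well = -spec.adhesion_depth * np.exp(
                -((z_ret - adhesion_center) ** 2) / (2.0 * spec.adhesion_width**2))
        else:
            well = np.where(z_ret == adhesion_center, -spec.adhesion_depth, 0.0)
    F_ret = F_ret_contact + well + spec.baseline_slope * (z_ret - z[0])
    if spec.noise_sd > 0:
        F_ret = F_ret + rng.normal(0.0, spec.noise_sd, z_ret.size)

    curve = ForceCurve(
        curve_id=curve_id,
        z_app_nm=z * 1e9,
        defl_app_nm=F_app / spec.k * 1e9,
        z_ret_nm=z_ret * 1e9,
        defl_ret_nm=F_ret / spec.k * 1e9,
        k=spec.k,
        R_um=spec.R * 1e6,
    )
    truth = CurveGroundTruth(
        curve_id=curve_id, E_true=spec.E_true, z0_true=z0, nu=spec.nu,
        k=spec.k, R=spec.R, adhesion_depth=spec.adhesion_depth,
        adhesion_center=adhesion_center, adhesion_width=spec.adhesion_width,
        hysteresis_factor=spec.hysteresis_factor,
        baseline_slope=spec.baseline_slope, noise_sd=spec.noise_sd,
        seed_key=seed_key,
    )
    return curve, truth


def generate_force_curve(spec: CurveGenSpec, curve_id: str = "curve0") -> tuple[ForceCurve, CurveGroundTruth]:
    """Generate one synthetic force curve and its ground-truth record."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    return _render_curve(spec, spec.z0_true, rng, curve_id, (spec.seed,))


def generate_curve_batch(spec: CurveGenSpec, n_regions: int, n_points: int,
                         n_replicates: int, sample: str = "s0",
                         z0_jitter: float = 5e-8,
                         age: str | None = None,
                         volume: str | None = None) -> CurveBatch:
    """Generate a region x point x replicate nest of curves for one sample.

    Each curve gets an independently jittered contact point (normal with sd
    ``z0_jitter``, clipped to stay inside the ramp) and fresh noise from a
    per-curve child seed derived from (seed, region, point, replicate), so
    batches are bit-reproducible and curves are statistically independent.
    """
    spec.validate()
    if min(n_regions, n_points, n_replicates) < 1:
        raise ValueError("hierarchy counts must all be >= 1")
    lo, hi = spec.z_range
    span = hi - lo
    records: list[CurveRecord] = []
    for r in range(n_regions):
        for p in range(n_points):
            for i in range(n_replicates):
                key = (spec.seed, r, p, i)
                rng = np.random.default_rng(np.random.SeedSequence(key))
                z0 = spec.z0_true
                if z0_jitter > 0:
                    z0 = float(np.clip(spec.z0_true + rng.normal(0.0, z0_jitter),
                                       lo + 0.05 * span, hi - 0.05 * span))
                cid = f"{sample}/r{r}/p{p}/i{i}"
                curve, truth = _render_curve(spec, z0, rng, cid, key)
                records.append(CurveRecord(sample, r, p, i, curve, truth))
    return CurveBatch(sample=sample, records=records, age=age, volume=volume)


# ---------------------------------------------------------------------------
# ECM intensity images
# ---------------------------------------------------------------------------

@dataclass
class ImageGenSpec:
    """Fiber- or blob-textured immunofluorescence image with an exact activated fraction."""

    shape: tuple[int, int] = (256, 256)
    bit_depth: int = 8
    background_level: float = 30.0
    signal_level: float = 200.0
    activated_fraction_true: float = 0.25
    texture: str = "fiber"
    noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.signal_level <= self.background_level:
            raise ValueError("signal_level must exceed background_level")
        if not 0.0 <= self.activated_fraction_true <= 1.0:
            raise ValueError("activated_fraction_true must be in [0, 1]")
        if self.texture not in ("fiber", "blob"):
            raise ValueError("texture must be 'fiber' or 'blob'")
        mx = 2**self.bit_depth - 1
        if not (0 <= self.background_level <= mx and 0 <= self.signal_level <= mx):
            raise ValueError("levels must lie within the bit-depth range")


def _texture_field(spec: ImageGenSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.shape
    canvas = np.zeros((h, w), dtype=float)
    if spec.texture == "fiber":
        n_streaks = max(30, (h * w) // 1200)
        for _ in range(n_streaks):
            r0, c0 = rng.integers(0, h), rng.integers(0, w)
            angle = rng.uniform(0, np.pi)
            length = rng.uniform(0.15, 0.5) * min(h, w)
            r1 = int(np.clip(r0 + length * np.sin(angle), 0, h - 1))
            c1 = int(np.clip(c0 + length * np.cos(angle), 0, w - 1))
            rr, cc = draw_line(int(r0), int(c0), r1, c1)
            canvas[rr, cc] += 1.0
        canvas = gaussian_filter(canvas, sigma=1.5)
    else:
        canvas = gaussian_filter(rng.normal(size=(h, w)), sigma=6.0)
    # infinitesimal dither so the activated-count cut never ties
    return canvas + rng.uniform(0.0, 1e-9, size=canvas.shape)


def generate_if_image(spec: ImageGenSpec) -> tuple[np.ndarray, dict]:
    """Generate a textured intensity image whose activated-pixel fraction is exact.

    The brightest ``round(activated_fraction_true * n_pixels)`` pixels of a
    random texture field are set to ``signal_level`` and the rest to
    ``background_level`` before additive noise, so before noise the fraction
    above the level midpoint equals the requested fraction exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_px = spec.shape[0] * spec.shape[1]
    n_act = int(round(spec.activated_fraction_true * n_px))
    if spec.activated_fraction_true > 0 and n_act < 1:
        raise ValueError("activated_fraction_true maps to fewer than 1 pixel for this shape")

    img = np.full(spec.shape, spec.background_level, dtype=float)
    if n_act > 0:
        tex = _texture_field(spec, rng)
        order = np.argsort(tex, axis=None)[::-1]
        img.flat[order[:n_act]] = spec.signal_level
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, spec.shape)
    mx = 2**spec.bit_depth - 1
    img = np.clip(np.rint(img), 0, mx).astype(np.uint8 if spec.bit_depth == 8 else np.uint16)

    truth = {
        "activated_fraction_true": spec.activated_fraction_true,
        "n_activated": n_act,
        "background_level": spec.background_level,
        "signal_level": spec.signal_level,
        "midpoint_threshold": 0.5 * (spec.background_level + spec.signal_level),
        "bit_depth": spec.bit_depth,
        "seed": spec.seed,
    }
    return img, truth


def generate_if_image_set(spec: ImageGenSpec, n_images: int,
                          fraction_cv: float = 0.02) -> list[tuple[np.ndarray, dict]]:
    """Generate an image group with per-image biological variability.

    Each image's activated fraction is the spec value times a multiplicative
    factor 1 + N(0, fraction_cv) (clipped to keep the fraction in (0, 1]), so
    the group mean stays centred on the spec value while within-group scatter
    is non-zero; per-image seeds derive from (seed, image index).
    """
    out = []
    for i in range(n_images):
        child = np.random.default_rng(np.random.SeedSequence((spec.seed, i)))
        factor = 1.0 + child.normal(0.0, fraction_cv) if fraction_cv > 0 else 1.0
        frac = float(np.clip(spec.activated_fraction_true * factor, 1e-6, 1.0))
        ispec = ImageGenSpec(**{**spec.__dict__,
                                "activated_fraction_true": frac,
                                "seed": int(child.integers(2**31))})
        out.append(generate_if_image(ispec))
    return out


# ---------------------------------------------------------------------------
# Cell fields (Hoechst / Ki67 / live / dead)
# ---------------------------------------------------------------------------

@dataclass
class CellImageGenSpec:
    """Multi-channel nuclei field with known Ki67-positive and live fractions."""

    shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 100
    nucleus_diameter_px: tuple[int, int] = (8, 14)
    ki67_fraction_true: float = 0.35
    live_fraction_true: float = 0.97
    min_separation_px: float = 16.0
    noise_sd: float = 2.0
    signal_level: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if not (0.0 <= self.ki67_fraction_true <= 1.0 and 0.0 <= self.live_fraction_true <= 1.0):
            raise ValueError("fractions must be in [0, 1]")
        d_lo, d_hi = self.nucleus_diameter_px
        if d_lo < 1 or d_hi < d_lo:
            raise ValueError("nucleus_diameter_px must be a valid (lo, hi) range")


def _place_centers(spec: CellImageGenSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.shape
    margin = spec.nucleus_diameter_px[1] / 2 + 1
    centers: list[tuple[float, float]] = []
    max_tries = 400 * max(spec.n_nuclei, 1)
    tries = 0
    while len(centers) < spec.n_nuclei:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} nuclei at min separation "
                f"{spec.min_separation_px}px in a {h}x{w} field")
        tries += 1
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= spec.min_separation_px**2 for r0, c0 in centers):
            centers.append((r, c))
    return np.array(centers).reshape(-1, 2)


def generate_cell_image(spec: CellImageGenSpec) -> tuple[np.ndarray, dict]:
    """Generate a 4-channel field: Hoechst (all nuclei), Ki67, live, dead.

    Channel 0 holds every nucleus; channel 1 marks round(ki67_fraction_true *
    n_nuclei) randomly chosen nuclei; channels 2/3 split the nuclei into
    round(live_fraction_true * n_nuclei) live vs the remaining dead. Ground
    truth lists each nucleus centroid, diameter and labels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    centers = _place_centers(spec, rng)
    n = spec.n_nuclei
    d_lo, d_hi = spec.nucleus_diameter_px
    diameters = rng.integers(d_lo, d_hi + 1, size=n) if n else np.zeros(0, dtype=int)

    n_ki67 = int(np.floor(spec.ki67_fraction_true * n + 0.5))
    n_live = int(np.floor(spec.live_fraction_true * n + 0.5))
    ki67_idx = set(rng.choice(n, size=n_ki67, replace=False).tolist()) if n_ki67 else set()
    live_idx = set(rng.choice(n, size=n_live, replace=False).tolist()) if n_live else set()

    stack = np.zeros((4, h, w), dtype=float)
    nuclei = []
    for i in range(n):
        r, c = centers[i]
        rad = diameters[i] / 2.0
        rr, cc = draw_disk((r, c), rad, shape=(h, w))
        stack[0, rr, cc] = spec.signal_level
        if i in ki67_idx:
            rr2, cc2 = draw_disk((r, c), max(rad * 0.6, 1.0), shape=(h, w))
            stack[1, rr2, cc2] = spec.signal_level
        ch = 2 if i in live_idx else 3
        stack[ch, rr, cc] = spec.signal_level
        nuclei.append({
            "centroid": [float(r), float(c)],
            "diameter_px": int(diameters[i]),
            "ki67": i in ki67_idx,
            "live": i in live_idx,
        })
    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, stack.shape)
    stack = np.clip(np.rint(stack), 0, 255).astype(np.uint8)

    truth = {
        "n_nuclei": n,
        "n_ki67_pos": n_ki67,
        "n_live": n_live,
        "n_dead": n - n_live,
        "ki67_fraction_true": spec.ki67_fraction_true,
        "live_fraction_true": spec.live_fraction_true,
        "signal_level": spec.signal_level,
        "nuclei": nuclei,
        "seed": spec.seed,
    }
    return stack, truth
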