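"""Synthetic phantoms and the blur + Poisson degradation protocol.

The phantoms stand in for the classic grayscale test photographs: each
kind combines sharp intensity jumps (where edge preservation matters)
with smooth affine ramps (where plain TV staircases and TGV^2 should
not).  Degradation follows the photon-limited imaging protocol: the
clean image is blurred with a stated PSF and every pixel of the result
is replaced by a Poisson draw with that blurred intensity as its mean,
so the noise variance equals the local signal level.

Everything is deterministic given a seed; fixture suites round-trip
bit-exactly through float32 TIFF files plus a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .blur import PSF, BlurOperator, psf_from_spec

__all__ = [
    "DegradationSpec",
    "Fixture",
    "make_phantom",
    "degrade",
    "make_fixture_suite",
    "save_suite",
    "load_suite",
    "PHANTOM_KINDS",
]

PHANTOM_KINDS = ("ramp-disks", "shapes", "piecewise-affine")

#: floor intensity of all phantoms — keeps Poisson means strictly positive
#: so the KL fidelity term stays finite everywhere
_FLOOR = 15.0


@dataclass(frozen=True)
class DegradationSpec:
    """Recipe for one blur + Poisson degradation.

    psf:   PSF instance or compact spec string ("gaussian:5,2", ...)
    peak:  maximum clean intensity used as the Poisson scale; the
           blurred image is rescaled so its brightest clean pixel has
           mean ``peak`` photons (255 leaves 8-bit images untouched)
    seed:  RNG seed of the Poisson draw
    """

    psf: "str | PSF" = "gaussian:5,2"
    peak: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak <= 0:
            raise ValueError("peak must be positive")


def make_phantom(height: int, width: int, kind: str = "ramp-disks",
                 seed: int = 0, peak: float = 255.0) -> np.ndarray:
    """Generate a clean nonnegative phantom in ``[0, peak]``.

    Kinds
    -----
    ramp-disks:
        A global affine ramp with two constant-offset disks confined to
        the right half; the left 40% of the image is purely affine
        (vanishing second differences), the disk rims are sharp jumps.
    shapes:
        Piecewise-constant rectangles and disks on a flat background.
    piecewise-affine:
        Two half-planes with different affine intensity functions,
        split by a seeded oblique line, plus one disk.
    """
    if height < 32 or width < 32:
        raise ValueError("phantom dimensions must be >= 32")
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; expected one of {PHANTOM_KINDS}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    lo, hi = _FLOOR, 0.92 * peak

    if kind == "ramp-disks":
        gx = rng.uniform(0.6, 1.0)
        gy = rng.uniform(-0.25, 0.25)
        ramp = gx * xx / width + gy * yy / height
        ramp = (ramp - ramp.min()) / (ramp.max() - ramp.min())
        u = lo + (hi - lo - 60.0) * ramp
        for _ in range(2):
            cx = rng.uniform(0.62 * width, 0.85 * width)
            cy = rng.uniform(0.2 * height, 0.8 * height)
            r = rng.uniform(0.06, 0.12) * min(height, width)
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
            u = u + mask * rng.uniform(35.0, 60.0)
    elif kind == "shapes":
        u = np.full((height, width), lo + rng.uniform(5.0, 20.0))
        for _ in range(3):
            x0, y0 = rng.uniform(0.05, 0.55, size=2)
            wfrac, hfrac = rng.uniform(0.15, 0.35, size=2)
            mask = ((xx >= x0 * width) & (xx < (x0 + wfrac) * width)
                    & (yy >= y0 * height) & (yy < (y0 + hfrac) * height))
            u = np.where(mask, rng.uniform(lo + 40.0, hi), u)
        cx, cy = rng.uniform(0.25, 0.75, size=2)
        r = rng.uniform(0.1, 0.18) * min(height, width)
        mask = (xx - cx * width) ** 2 + (yy - cy * height) ** 2 <= r**2
        u = np.where(mask, rng.uniform(lo + 40.0, hi), u)
    else:  # piecewise-affine
        nx, ny = rng.normal(size=2)
        norm = np.hypot(nx, ny) or 1.0
        nx, ny = nx / norm, ny / norm
        side = (nx * (xx - width / 2) + ny * (yy - height / 2)) >= 0
        ramp_a = rng.uniform(0.4, 1.0) * xx / width + rng.uniform(-0.4, 0.4) * yy / height
        ramp_b = rng.uniform(-1.0, -0.4) * xx / width + rng.uniform(-0.4, 0.4) * yy / height
        span = hi - lo - 50.0

        def scale01(r):
            return (r - r.min()) / max(r.max() - r.min(), 1e-9)

        u = np.where(side, lo + span * scale01(ramp_a), lo + 40.0 + span * scale01(ramp_b))
        cx, cy = rng.uniform(0.3, 0.7, size=2)
        r = rng.uniform(0.08, 0.14) * min(height, width)
        mask = (xx - cx * width) ** 2 + (yy - cy * height) ** 2 <= r**2
        u = u + mask * rng.uniform(25.0, 45.0)

    # affine map onto [floor, peak]: keeps flats flat and ramps affine, and
    # makes the brightest pixel exactly `peak`, so degrade()'s peak/max(u)
    # Poisson scaling is unity (counts live on the image's own scale)
    u = lo + (u - u.min()) * (peak - lo) / max(u.max() - u.min(), 1e-9)
    return np.clip(u, 0.0, peak)


def degrade(u: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Blur a clean image and draw each pixel from a Poisson law.

    The blurred image is scaled by ``peak / max(u)`` before sampling so
    the brightest clean pixel corresponds to ``peak`` expected photons;
    the returned counts stay on that scale (integer-valued floats).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("clean image must be nonnegative")
    psf = psf_from_spec(spec.psf)
    K = BlurOperator(psf, u.shape)
    blurred = np.clip(K.apply(u), 0.0, None)
    umax = u.max()
    scale = spec.peak / umax if umax > 0 else 1.0
    rng = np.random.default_rng(spec.seed)
    return rng.poisson(blurred * scale).astype(float)


@dataclass
class Fixture:
    """One (clean, PSF, degraded) triple of the synthetic suite."""

    name: str
    clean: np.ndarray
    degraded: np.ndarray
    psf_spec: str
    phantom_kind: str
    phantom_seed: int
    noise_seed: int
    peak: float = 255.0

    @property
    def psf(self) -> PSF:
        return psf_from_spec(self.psf_spec)


#: the three degradation protocols paired with the phantom kind used
_FAMILIES = (
    ("gaussian:5,2", "ramp-disks"),
    ("box:5", "shapes"),
    ("motion:2,45", "piecewise-affine"),
)


def make_fixture_suite(seed: int, sizes: tuple[int, ...] = (64, 128),
                       outdir: "str | Path | None" = None) -> list[Fixture]:
    """Build the standard fixture suite: all three PSF families at each size.

    Child seeds are derived from ``seed`` through a SeedSequence so the
    suite is fully reproducible; if ``outdir`` is given the suite is
    also written there (float32 TIFFs + manifest.json).
    """
    ss = np.random.SeedSequence(seed)
    n = 2 * len(sizes) * len(_FAMILIES)
    states = [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint32)]
    fixtures: list[Fixture] = []
    i = 0
    for size in sizes:
        for psf_spec, kind in _FAMILIES:
            phantom_seed, noise_seed = states[i], states[i + 1]
            i += 2
            clean = make_phantom(size, size, kind=kind, seed=phantom_seed)
            degraded = degrade(clean, DegradationSpec(psf=psf_spec, seed=noise_seed))
            name = f"{kind}_{psf_spec.replace(':', '-').replace(',', '-')}_{size}"
            fixtures.append(Fixture(name=name, clean=clean, degraded=degraded,
                                    psf_spec=psf_spec, phantom_kind=kind,
                                    phantom_seed=phantom_seed, noise_seed=noise_seed))
    if outdir is not None:
        save_suite(fixtures, outdir)
    return fixtures


def save_suite(fixtures: list[Fixture], outdir: "str | Path") -> Path:
    """Write a fixture suite as float32 TIFF pairs plus a JSON manifest."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for fx in fixtures:
        clean_file = f"{fx.name}_clean.tif"
        degraded_file = f"{fx.name}_degraded.tif"
        tifffile.imwrite(outdir / clean_file, fx.clean.astype(np.float32))
        tifffile.imwrite(outdir / degraded_file, fx.degraded.astype(np.float32))
        manifest.append({
            "name": fx.name,
            "clean": clean_file,
            "degraded": degraded_file,
            "psf": fx.psf_spec,
            "phantom_kind": fx.phantom_kind,
            "phantom_seed": fx.phantom_seed,
            "noise_seed": fx.noise_seed,
            "peak": fx.peak,
        })
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir / "manifest.json"


def load_suite(outdir: "str | Path") -> list[Fixture]:
    """Reload a fixture suite written by :func:`save_suite`."""
    import tifffile

    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    fixtures = []
    for entry in manifest:
        fixtures.append(Fixture(
            name=entry["name"],
            clean=np.asarray(tifffile.imread(outdir / entry["clean"]), dtype=np.float32),
            degraded=np.asarray(tifffile.imread(outdir / entry["degraded"]), dtype=np.float32),
            psf_spec=entry["psf"],
            phantom_kind=entry["phantom_kind"],
            phantom_seed=entry["phantom_seed"],
            noise_seed=entry["noise_seed"],
            peak=entry["peak"],
        ))
    return fixtures
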