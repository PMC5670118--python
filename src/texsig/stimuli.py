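"""Stimulus construction: phase-randomized (SM) images and structured textures.

Electrophysiology studies of texture selectivity contrast two stimulus
classes derived from the same source image: a *spectrally matched* (SM)
image, obtained by randomizing the phases of the Fourier components while
keeping the amplitude spectrum, and a *correlation-matched* (CM) image,
synthesized to share the source's higher-order statistics (correlations of
linear and energy filter responses across position, scale, and
orientation).  This module provides the SM construction exactly, and a
generative stand-in for the CM/natural corpus: structured textures built
from oriented quadrature elements laid along smooth contours, with
co-located elements repeated across scales so that the images carry the
cross-position and cross-scale dependencies that phase scrambling destroys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import qmc
from skimage.transform import resize as _sk_resize

__all__ = [
    "GrayImage",
    "StimulusPair",
    "StimulusCorpus",
    "FamilyParams",
    "phase_randomize",
    "synth_texture",
    "build_corpus",
    "preprocess",
    "save_corpus",
    "load_corpus",
    "import_corpus",
]


@dataclass
class GrayImage:
    """A 2-D real-valued grayscale stimulus with corpus bookkeeping labels."""

    pixels: np.ndarray
    family_id: int = 0
    image_id: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D array, got ndim={self.pixels.ndim}")
        h, w = self.pixels.shape
        if h < 8 or w < 8:
            raise ValueError(f"image must be at least 8x8, got {h}x{w}")
        bad = int(np.size(self.pixels) - np.isfinite(self.pixels).sum())
        if bad:
            raise ValueError(f"image contains {bad} non-finite pixel(s)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class StimulusPair:
    """A structured (CM-role) image and its phase-scrambled (SM) counterpart."""

    cm: GrayImage
    sm: GrayImage
    pair_id: int = 0

    def __post_init__(self) -> None:
        if self.cm.shape != self.sm.shape:
            raise ValueError(
                f"cm and sm dimensions differ: {self.cm.shape} vs {self.sm.shape}"
            )

    @property
    def family_id(self) -> int:
        return self.cm.family_id


@dataclass
class StimulusCorpus:
    """Families x images of (structured, phase-scrambled) pairs."""

    pairs: list[StimulusPair]
    n_families: int
    n_per_family: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pairs) != self.n_families * self.n_per_family:
            raise ValueError(
                f"expected {self.n_families * self.n_per_family} pairs, "
                f"got {len(self.pairs)}"
            )
        for p in self.pairs:
            if not (1 <= p.family_id <= self.n_families):
                raise ValueError(
                    f"pair {p.pair_id} carries family_id {p.family_id} "
                    f"outside 1..{self.n_families}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def family_ids(self) -> np.ndarray:
        return np.array([p.family_id for p in self.pairs], dtype=int)

    def cm_images(self) -> list[GrayImage]:
        return [p.cm for p in self.pairs]

    def sm_images(self) -> list[GrayImage]:
        return [p.sm for p in self.pairs]


# ---------------------------------------------------------------------------
# Phase randomization
# ---------------------------------------------------------------------------

def _conjugate_bins(a: np.ndarray) -> np.ndarray:
    """Return b with b[u, v] = a[(-u) % H, (-v) % W]."""
    return np.roll(a[::-1, ::-1], (1, 1), axis=(0, 1))


def phase_randomize(img: GrayImage, seed: int,
                    randomize_nyquist_sign: bool = True) -> GrayImage:
    """Randomize Fourier phases of an image, preserving the amplitude spectrum.

    Phases are perturbed by an exactly antisymmetric random field
    ``phi(k) = theta(k) - theta(-k)`` with ``theta`` i.i.d. uniform, which
    keeps the spectrum Hermitian so the output is real to machine precision.
    The DC bin is untouched (the image mean is preserved); the self-conjugate
    Nyquist bins of even-sized images can only change sign, which is applied
    as an explicit random sign flip.

    Parameters
    ----------
    img : GrayImage
        Source image.  Both dimensions must be even.
    seed : int
        Seed for the phase draw.
    randomize_nyquist_sign : bool
        Whether to flip the sign of the self-conjugate Nyquist bins at
        random (the only phase freedom those bins have).
    """
    p = img.pixels
    h, w = p.shape
    if h % 2 or w % 2:
        raise ValueError(f"image dimensions must be even, got {h}x{w}")
    rng = np.random.default_rng(seed)
    F = np.fft.fft2(p)
    theta = rng.uniform(-np.pi, np.pi, size=(h, w))
    phi = theta - _conjugate_bins(theta)  # exactly antisymmetric
    out_F = F * np.exp(1j * phi)
    # Self-conjugate bins: (0,0), (0,W/2), (H/2,0), (H/2,W/2).  phi is 0
    # there by construction; optionally randomize the residual sign freedom.
    if randomize_nyquist_sign:
        for u, v in ((0, w // 2), (h // 2, 0), (h // 2, w // 2)):
            out_F[u, v] *= rng.choice((-1.0, 1.0))
    out = np.fft.ifft2(out_F)
    resid = np.abs(out.imag).max()
    norm = np.linalg.norm(p)
    if norm > 0 and resid > 1e-9 * norm:
        raise AssertionError(
            f"Hermitian symmetry violated: imaginary residue {resid:.3g}"
        )
    return GrayImage(out.real, family_id=img.family_id, image_id=img.image_id)


# ---------------------------------------------------------------------------
# Structured texture synthesis (CM-role stand-in)
# ---------------------------------------------------------------------------

@dataclass
class FamilyParams:
    """Generative knobs for one texture family.

    density : float in [0, 1]
        Surface density of oriented elements (0 gives a pure noise field).
    orientation_concentration : float >= 0
        von Mises concentration of contour orientations around
        ``mean_orientation``; 0 = isotropic.
    curvature : float in [0, 1]
        How strongly a contour bends per step.
    scale_coupling : float in [0, 1]
        Amplitude of the coarse-scale element added at the location (and
        orientation) of each fine-scale element; 0 decouples the scales.
    mean_orientation : float
        Preferred contour orientation, radians.
    """

    density: float = 0.5
    orientation_concentration: float = 2.0
    curvature: float = 0.2
    scale_coupling: float = 0.7
    mean_orientation: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must be in [0, 1], got {self.density}")
        if self.orientation_concentration < 0:
            raise ValueError("orientation_concentration must be >= 0")
        if not 0.0 <= self.curvature <= 1.0:
            raise ValueError(f"curvature must be in [0, 1], got {self.curvature}")
        if not 0.0 <= self.scale_coupling <= 1.0:
            raise ValueError(
                f"scale_coupling must be in [0, 1], got {self.scale_coupling}"
            )


def _gabor_patch(wavelength: float, sigma: float, theta: float,
                 phase: float) -> np.ndarray:
    half = int(np.ceil(2.0 * sigma))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    rot = xx * np.cos(theta) + yy * np.sin(theta)
    env = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
    return env * np.cos(2.0 * np.pi * rot / wavelength + phase)


def synth_texture(params: FamilyParams, seed: int, size: int = 64,
                  noise_amplitude: float = 0.08, wavelength: float = 5.0,
                  rms: float | None = 0.02) -> GrayImage:
    """Render a structured texture with controllable higher-order statistics.

    Oriented elements (Gabor patches at the base ``wavelength``) are placed
    along smooth contours whose direction diffuses at a rate set by
    ``curvature``.  When ``scale_coupling`` > 0 every element is accompanied
    by a one-octave-coarser element at the same location and orientation,
    injecting the cross-scale energy correlations that a phase scramble
    cannot preserve.  A weak Gaussian noise floor keeps the image spectrally
    broadband.

    The output is mean-subtracted and scaled to RMS contrast ``rms``
    (pass ``None`` to keep raw element amplitudes).  The default contrast
    is calibrated so that the reference sparse-coding penalties operate in
    a genuinely sparse regime: texture elements clear the soft threshold
    while the spatially spread energy of a phase scramble mostly does not
    — the regime in which selective units can express a structure
    preference at all.
    """
    params.validate()
    if size < 8 or size % 2:
        raise ValueError(f"size must be even and >= 8, got {size}")
    rng = np.random.default_rng(seed)
    canvas = noise_amplitude * rng.standard_normal((size, size))
    lam_fine, lam_coarse = wavelength, 2.0 * wavelength
    sig_fine, sig_coarse = 0.4 * lam_fine, 0.4 * lam_coarse
    fine = {}
    coarse = {}

    # element count scales with density and area (in element-size units)
    n_elements = int(round(params.density * (size / wavelength) ** 2))
    steps_per_contour = 5
    n_contours = n_elements // steps_per_contour

    kappa = params.orientation_concentration
    for _ in range(n_contours):
        y, x = rng.uniform(0, size, size=2)
        if kappa > 0:
            direction = rng.vonmises(2.0 * params.mean_orientation, kappa) / 2.0
        else:
            direction = rng.uniform(-np.pi / 2, np.pi / 2)
        polarity = rng.choice((-1.0, 1.0))
        for _ in range(steps_per_contour):
            key = round(direction / 0.05) * 0.05
            if key not in fine:
                fine[key] = _gabor_patch(lam_fine, sig_fine, key, 0.0)
                coarse[key] = _gabor_patch(lam_coarse, sig_coarse, key, 0.0)
            _stamp(canvas, fine[key], y, x, polarity)
            if params.scale_coupling > 0:
                _stamp(canvas, coarse[key], y, x,
                       polarity * params.scale_coupling)
            # advance along the contour, bending by the curvature
            step = lam_fine * 0.9
            y += step * np.sin(direction + np.pi / 2)
            x += step * np.cos(direction + np.pi / 2)
            direction += params.curvature * rng.standard_normal() * 0.8
    if rms is not None:
        canvas -= canvas.mean()
        sd = canvas.std()
        if sd > 0:
            canvas *= rms / sd
    return GrayImage(canvas)


def _stamp(canvas: np.ndarray, patch: np.ndarray, y: float, x: float,
           amplitude: float) -> None:
    """Add ``amplitude * patch`` centred at (y, x), with toroidal wrap."""
    size = canvas.shape[0]
    half = patch.shape[0] // 2
    iy = int(round(y)) % size
    ix = int(round(x)) % size
    ys = (np.arange(-half, half + 1) + iy) % size
    xs = (np.arange(-half, half + 1) + ix) % size
    canvas[np.ix_(ys, xs)] += amplitude * patch


# ---------------------------------------------------------------------------
# Corpus construction
# ---------------------------------------------------------------------------

_PARAM_RANGES = {
    "density": (0.2, 0.7),
    "orientation_concentration": (0.5, 4.0),
    "curvature": (0.05, 0.5),
    "scale_coupling": (0.3, 1.0),
}


def sample_family_params(n_families: int, seed: int) -> list[FamilyParams]:
    """Draw family parameter records from distinct regions of knob space.

    A Latin hypercube over the four knobs guarantees the families are spread
    out (so per-family preference orderings are meaningful); the preferred
    orientation is assigned on an even grid.
    """
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    u = sampler.random(n=n_families)
    out = []
    for i in range(n_families):
        kw = {}
        for j, (name, (lo, hi)) in enumerate(_PARAM_RANGES.items()):
            kw[name] = lo + (hi - lo) * u[i, j]
        kw["mean_orientation"] = np.pi * i / n_families - np.pi / 2
        out.append(FamilyParams(**kw))
    return out


def build_corpus(n_families: int, n_per_family: int, size: int = 64,
                 seed: int = 0, family_seed: int | None = None
                 ) -> StimulusCorpus:
    """Build a full corpus of (structured, phase-scrambled) pairs.

    Per image, a fresh synthesis seed and a fresh scrambling seed are spawned
    deterministically from ``seed``; all seeds are recorded in the corpus
    metadata.  ``family_seed`` fixes the family parameter draw separately,
    so a second corpus (e.g. a training set disjoint from the evaluation
    pairs) can share the same texture families.
    """
    if n_families < 1 or n_per_family < 1:
        raise ValueError("counts must be >= 1")
    families = sample_family_params(
        n_families, seed if family_seed is None else family_seed)
    root = np.random.SeedSequence(seed)
    image_seeds = root.spawn(n_families * n_per_family)
    pairs = []
    seed_log = []
    k = 0
    for fam_idx, params in enumerate(families, start=1):
        for img_idx in range(1, n_per_family + 1):
            synth_seed, scram_seed = [
                int(s.generate_state(1)[0] % (2 ** 31))
                for s in image_seeds[k].spawn(2)
            ]
            cm = synth_texture(params, seed=synth_seed, size=size)
            cm.family_id, cm.image_id = fam_idx, img_idx
            sm = phase_randomize(cm, seed=scram_seed)
            pairs.append(StimulusPair(cm=cm, sm=sm, pair_id=k))
            seed_log.append({"pair_id": k, "family_id": fam_idx,
                             "synth_seed": synth_seed,
                             "scramble_seed": scram_seed})
            k += 1
    meta = {
        "seed": seed,
        "size": size,
        "interpolation": "bilinear",
        "families": [vars(f) for f in families],
        "image_seeds": seed_log,
    }
    return StimulusCorpus(pairs=pairs, n_families=n_families,
                          n_per_family=n_per_family, metadata=meta)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _resize(p: np.ndarray, size: int) -> np.ndarray:
    if p.shape == (size, size):
        return p
    down = size < min(p.shape)
    return _sk_resize(p, (size, size), order=1, anti_aliasing=down,
                      preserve_range=True, mode="reflect")


def preprocess(img: GrayImage, working_size: int = 128,
               model_size: int = 224) -> GrayImage:
    """Resize to the working size, subtract the mean, resize to the model size.

    Mirrors the standard preparation of texture stimuli for hierarchical
    models: statistics are defined at a working resolution, the per-image
    mean is removed there, and the result is upsampled (bilinear) to the
    model's input resolution.
    """
    if working_size < 8 or model_size < 8:
        raise ValueError("target sizes must be >= 8")
    p = _resize(img.pixels, working_size)
    p = p - p.mean()
    p = _resize(p, model_size)
    return GrayImage(p, family_id=img.family_id, image_id=img.image_id)


def preprocess_corpus(corpus: StimulusCorpus, working_size: int,
                      model_size: int) -> StimulusCorpus:
    pairs = [
        StimulusPair(cm=preprocess(p.cm, working_size, model_size),
                     sm=preprocess(p.sm, working_size, model_size),
                     pair_id=p.pair_id)
        for p in corpus.pairs
    ]
    meta = dict(corpus.metadata)
    meta["preprocess"] = {"working_size": working_size, "model_size": model_size}
    return StimulusCorpus(pairs=pairs, n_families=corpus.n_families,
                          n_per_family=corpus.n_per_family, metadata=meta)


# ---------------------------------------------------------------------------
# I/O: raw array container (.npy) + JSON manifest; optional PNG export
# ---------------------------------------------------------------------------

def save_corpus(corpus: StimulusCorpus, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in corpus.pairs:
        cm_path = out / f"pair{p.pair_id:05d}_cm.npy"
        sm_path = out / f"pair{p.pair_id:05d}_sm.npy"
        np.save(cm_path, p.cm.pixels)
        np.save(sm_path, p.sm.pixels)
        entries.append({
            "pair_id": p.pair_id,
            "family_id": p.family_id,
            "image_id": p.cm.image_id,
            "cm": cm_path.name,
            "sm": sm_path.name,
        })
    manifest = {
        "n_families": corpus.n_families,
        "n_per_family": corpus.n_per_family,
        "metadata": corpus.metadata,
        "pairs": entries,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, default=float))
    return mpath


def load_corpus(manifest_path: str | Path) -> StimulusCorpus:
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    base = mpath.parent
    pairs = []
    for e in manifest["pairs"]:
        cm = GrayImage(np.load(base / e["cm"]), family_id=e["family_id"],
                       image_id=e["image_id"])
        sm = GrayImage(np.load(base / e["sm"]), family_id=e["family_id"],
                       image_id=e["image_id"])
        pairs.append(StimulusPair(cm=cm, sm=sm, pair_id=e["pair_id"]))
    return StimulusCorpus(pairs=pairs, n_families=manifest["n_families"],
                          n_per_family=manifest["n_per_family"],
                          metadata=manifest.get("metadata", {}))


def import_corpus(cm_dir: str | Path, sm_dir: str | Path,
                  n_families: int, n_per_family: int) -> StimulusCorpus:
    """Ingest externally synthesized CM/SM image directories.

    Files are matched by sorted name across the two directories; images may
    be PNG (8- or 16-bit grayscale) or .npy arrays.  Family labels are
    assigned in blocks of ``n_per_family`` in sorted order.
    """
    from imageio.v3 import imread

    def _read(path: Path) -> np.ndarray:
        if path.suffix == ".npy":
            return np.load(path)
        arr = imread(path)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        return arr.astype(float)

    cm_files = sorted(p for p in Path(cm_dir).iterdir()
                      if p.suffix in (".png", ".npy"))
    sm_files = sorted(p for p in Path(sm_dir).iterdir()
                      if p.suffix in (".png", ".npy"))
    if len(cm_files) != len(sm_files):
        raise ValueError(
            f"{len(cm_files)} CM files but {len(sm_files)} SM files"
        )
    pairs = []
    for k, (cf, sf) in enumerate(zip(cm_files, sm_files)):
        fam = k // n_per_family + 1
        idx = k % n_per_family + 1
        cm = GrayImage(_read(cf), family_id=fam, image_id=idx)
        sm = GrayImage(_read(sf), family_id=fam, image_id=idx)
        pairs.append(StimulusPair(cm=cm, sm=sm, pair_id=k))
    return StimulusCorpus(pairs=pairs, n_families=n_families,
                          n_per_family=n_per_family,
                          metadata={"source": [str(cm_dir), str(sm_dir)]})
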