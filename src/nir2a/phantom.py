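"""Synthetic paired NIR-I / NIR-IIa vascular phantoms.

Each phantom starts from one random branching vessel tree rasterized with a
Gaussian cross-section.  The NIR-IIa channel is that rasterization under a
narrow scattering point-spread function (long-wave imaging: little
scattering, little autofluorescence).  The NIR-I channel is the *same*
rasterization under a wide PSF, plus a smooth autofluorescence field, plus a
bright elliptical hepatic hotspot — the three degradations that make
short-wave in vivo angiograms low-contrast.  Because both channels come from
a single rasterization, the pair is co-registered by construction and the
vessel mask is exact ground truth.

Every operation is a pure function of (arguments, seed): regeneration is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import DivisibilityError, Nir2aError, ValidationError

GENERATOR_VERSION = "1.0"

#: images must be divisible by 40: three stride-2 convolutions (factor 8)
#: followed by 5x5 token patching.
SIZE_DIVISOR = 40


def _check_size(size):
    h, w = size
    if h < SIZE_DIVISOR or w < SIZE_DIVISOR or h % SIZE_DIVISOR or w % SIZE_DIVISOR:
        raise DivisibilityError(
            f"image size {size} must be >= {SIZE_DIVISOR} and divisible by "
            f"{SIZE_DIVISOR} (three stride-2 convolutions then 5x5 patches)")


# ---------------------------------------------------------------------------
# vessel trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchingConfig:
    """Growth rules for the random vessel tree.

    Defaults produce 2-4 coarse stems that taper into sub-1.5-px
    microvessels, covering a few percent of a 120x120 frame.
    """
    n_stems: int = 3
    branch_prob: float = 0.4
    radius_decay: float = 0.82
    angle_jitter: float = 0.45       # radians, sd of direction noise
    min_radius: float = 0.7          # px, growth stops below this
    initial_radius: float = 3.2      # px
    segment_length: tuple = (10.0, 22.0)  # px, uniform range
    max_depth: int = 9

    def validate(self):
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValidationError("branch_prob must lie in [0, 1]")
        if not 0.0 < self.radius_decay <= 1.0:
            raise ValidationError("radius_decay must lie in (0, 1]")
        if self.n_stems < 1 or self.initial_radius <= 0 or self.min_radius <= 0:
            raise ValidationError("degenerate branching configuration")


@dataclass(frozen=True)
class Segment:
    start: tuple
    end: tuple
    radius: float


@dataclass(frozen=True)
class VesselTree:
    segments: tuple
    image_size: tuple
    seed: int

    def __post_init__(self):
        if not self.segments:
            raise ValidationError("a vessel tree needs >= 1 segment")
        h, w = self.image_size
        for s in self.segments:
            for p in (s.start, s.end):
                if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
                    raise ValidationError(f"endpoint {p} outside image")
            if s.radius <= 0:
                raise ValidationError("segment radius must be positive")

    def widest_segment(self) -> Segment:
        return max(self.segments, key=lambda s: s.radius)

    def summary(self) -> dict:
        radii = [s.radius for s in self.segments]
        return {"n_segments": len(self.segments),
                "max_radius": max(radii), "min_radius": min(radii),
                "seed": self.seed}


def grow_vessel_tree(size, seed: int,
                     params: BranchingConfig | None = None) -> VesselTree:
    """Grow a random branching vessel tree inside ``size`` = (H, W)."""
    params = params or BranchingConfig()
    params.validate()
    _check_size(size)
    h, w = size
    rng = np.random.default_rng(seed)
    segments = []

    def clip(p):
        return (float(np.clip(p[0], 0, h - 1)), float(np.clip(p[1], 0, w - 1)))

    # stems enter from a random border point heading inward
    stack = []
    for _ in range(params.n_stems):
        edge = rng.integers(4)
        t = rng.uniform(0.1, 0.9)
        if edge == 0:
            start, ang = (0.0, t * (w - 1)), np.pi / 2
        elif edge == 1:
            start, ang = (float(h - 1), t * (w - 1)), -np.pi / 2
        elif edge == 2:
            start, ang = (t * (h - 1), 0.0), 0.0
        else:
            start, ang = (t * (h - 1), float(w - 1)), np.pi
        ang += rng.normal(0, params.angle_jitter)
        stack.append((start, ang, params.initial_radius, 0))

    while stack:
        start, ang, radius, depth = stack.pop()
        if radius < params.min_radius or depth >= params.max_depth:
            continue
        length = rng.uniform(*params.segment_length)
        end_raw = (start[0] + length * np.sin(ang),
                   start[1] + length * np.cos(ang))
        end = clip(end_raw)
        if end == tuple(start):
            continue
        segments.append(Segment(tuple(start), end, float(radius)))
        hit_border = (end[0] != end_raw[0]) or (end[1] != end_raw[1])
        if hit_border:
            continue
        # continuation keeps the decayed radius and a jittered direction
        cont_ang = ang + rng.normal(0, params.angle_jitter)
        branching = rng.random() < params.branch_prob
        stack.append((end, cont_ang, radius * params.radius_decay,
                      depth + 1))
        if branching:
            side = rng.choice((-1.0, 1.0))
            branch_ang = ang + side * rng.uniform(0.4, 0.9)
            stack.append((end, branch_ang,
                          radius * params.radius_decay * 0.85, depth + 1))

    if not segments:  # extreme configs: keep at least one stem segment
        segments.append(Segment((h / 2 - 10, w / 2), (h / 2 + 10, w / 2),
                                params.initial_radius))
    return VesselTree(tuple(segments), (h, w), seed)


def rasterize_tree(tree: VesselTree):
    """Render the tree: (profile in [0,1] with Gaussian cross-section,
    boolean vessel mask at distance <= radius).

    The cross-section sigma is radius/2, so the rendered vessel FWHM is
    ~1.18x the nominal radius; segments combine by maximum.
    """
    h, w = tree.image_size
    profile = np.zeros((h, w), np.float64)
    mask = np.zeros((h, w), bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for seg in tree.segments:
        a = np.array(seg.start)
        b = np.array(seg.end)
        pad = int(np.ceil(3 * seg.radius + 2))
        r0 = max(int(min(a[0], b[0])) - pad, 0)
        r1 = min(int(max(a[0], b[0])) + pad + 1, h)
        c0 = max(int(min(a[1], b[1])) - pad, 0)
        c1 = min(int(max(a[1], b[1])) + pad + 1, w)
        y = yy[r0:r1, c0:c1]
        x = xx[r0:r1, c0:c1]
        ab = b - a
        denom = float(ab @ ab)
        t = ((y - a[0]) * ab[0] + (x - a[1]) * ab[1]) / denom
        t = np.clip(t, 0.0, 1.0)
        d2 = (y - (a[0] + t * ab[0])) ** 2 + (x - (a[1] + t * ab[1])) ** 2
        sigma = seg.radius / 2.0
        np.maximum(profile[r0:r1, c0:c1],
                   np.exp(-d2 / (2 * sigma * sigma)),
                   out=profile[r0:r1, c0:c1])
        mask[r0:r1, c0:c1] |= d2 <= seg.radius ** 2
    return profile, mask


# ---------------------------------------------------------------------------
# degradation physics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegradationParams:
    """Optics and camera model for the two imaging windows.

    The NIR-I channel sees a wider scattering PSF, a smooth autofluorescence
    field and a hepatic hotspot; the NIR-IIa channel sees only mild blur.
    Amplitudes are fractions of the vessel peak intensity; noise is Poisson
    shot noise at ``noise_poisson_scale`` photons per intensity unit plus
    additive Gaussian read noise.
    """
    psf_sigma_nir1: float = 3.0
    psf_sigma_nir2a: float = 0.6
    autofluor_amplitude: float = 0.8
    autofluor_correlation_length: float = 8.0
    hotspot_amplitude: float = 0.9
    hotspot_axes: tuple = (16.0, 11.0)
    noise_gaussian_sd: float = 0.01
    noise_poisson_scale: float = 2000.0
    vessel_peak: float = 0.85
    background_floor: float = 0.22

    def validate(self):
        if not self.psf_sigma_nir1 > self.psf_sigma_nir2a > 0:
            raise ValidationError(
                "need psf_sigma_nir1 > psf_sigma_nir2a > 0 (the short-wave "
                "window scatters more)")
        for name in ("autofluor_amplitude", "hotspot_amplitude",
                     "noise_gaussian_sd", "noise_poisson_scale"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.vessel_peak > self.background_floor >= 0:
            raise ValidationError("need vessel_peak > background_floor >= 0")


#: parameter set emulating an ICG-like acquisition: stronger skin
#: autofluorescence and a different hepatic hotspot than the defaults.
ICG_LIKE = DegradationParams(autofluor_amplitude=0.95,
                             hotspot_amplitude=0.55,
                             hotspot_axes=(20.0, 14.0))


@dataclass(frozen=True)
class PhantomPair:
    nir1: np.ndarray
    nir2a: np.ndarray
    vessel_mask: np.ndarray
    metadata: dict

    def __post_init__(self):
        if not (self.nir1.shape == self.nir2a.shape
                == self.vessel_mask.shape):
            raise ValidationError("pair images and mask must share a shape")
        _check_size(self.nir1.shape)
        frac = self.vessel_mask.mean()
        if not 0.01 <= frac <= 0.30:
            raise ValidationError(
                f"vessel mask occupancy {frac:.3f} outside [0.01, 0.30]")


def _camera_noise(img, params: DegradationParams, rng):
    out = img
    if params.noise_poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) *
                          params.noise_poisson_scale) / params.noise_poisson_scale
    if params.noise_gaussian_sd > 0:
        out = out + rng.normal(0.0, params.noise_gaussian_sd, img.shape)
    return out


def render_pair(tree: VesselTree, params: DegradationParams | None = None,
                seed: int = 0) -> PhantomPair:
    """Render the co-registered (NIR-I, NIR-IIa) pair for one vessel tree."""
    params = params or DegradationParams()
    params.validate()
    h, w = tree.image_size
    rng = np.random.default_rng(seed)
    profile, mask = rasterize_tree(tree)
    ideal = params.background_floor + \
        (params.vessel_peak - params.background_floor) * profile

    nir2a = ndimage.gaussian_filter(ideal, params.psf_sigma_nir2a)
    nir2a = _camera_noise(nir2a, params, rng)

    nir1 = ndimage.gaussian_filter(ideal, params.psf_sigma_nir1)
    if params.autofluor_amplitude > 0:
        f = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                    params.autofluor_correlation_length)
        f = (f - f.min()) / (f.max() - f.min() + 1e-12)
        nir1 = nir1 + params.autofluor_amplitude * params.vessel_peak * f
    if params.hotspot_amplitude > 0:
        # hepatic hotspot: one elliptical Gaussian in the central band
        cy = rng.uniform(0.45, 0.75) * (h - 1)
        cx = rng.uniform(0.3, 0.7) * (w - 1)
        ay, ax = params.hotspot_axes
        yy, xx = np.mgrid[0:h, 0:w]
        blob = np.exp(-(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2) / 2)
        nir1 = nir1 + params.hotspot_amplitude * params.vessel_peak * blob
    nir1 = _camera_noise(nir1, params, rng)

    meta = {"seed": int(seed), "degradation": asdict(params),
            "tree": tree.summary(), "saturation_warning": False}
    for name, img in (("nir1", nir1), ("nir2a", nir2a)):
        sat = float((img >= 1.0).mean())
        if sat > 0.05:
            meta["saturation_warning"] = True
            meta[f"saturated_fraction_{name}"] = sat
    nir1 = np.clip(nir1, 0.0, 1.0)
    nir2a = np.clip(nir2a, 0.0, 1.0)
    return PhantomPair(nir1, nir2a, mask, meta)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    pair_id: str
    nir1: str
    nir2a: str
    mask: str
    seed: int
    profile_line: tuple  # ((r0,c0),(r1,c1)) across the widest vessel
    widest_radius: float


@dataclass(frozen=True)
class DatasetManifest:
    entries: tuple
    split: dict              # pair_id -> "train" | "val" | "test"
    generator_version: str
    base_seed: int
    size: tuple
    root: Path = field(compare=False, default=Path("."))

    def ids_for(self, part: str):
        return [e.pair_id for e in self.entries if self.split[e.pair_id] == part]

    def entry(self, pair_id: str) -> ManifestEntry:
        for e in self.entries:
            if e.pair_id == pair_id:
                return e
        raise KeyError(pair_id)

    def path(self, rel: str) -> Path:
        return self.root / rel


def _profile_line_for(tree: VesselTree, psf_sigma: float):
    """Perpendicular cross-section through the widest segment's midpoint,
    long enough to reach baseline on both sides after blurring."""
    seg = tree.widest_segment()
    a = np.array(seg.start)
    b = np.array(seg.end)
    mid = (a + b) / 2
    d = b - a
    d = d / (np.hypot(*d) + 1e-12)
    perp = np.array([-d[1], d[0]])
    half = max(4.0 * seg.radius + 4.0 * psf_sigma, 10.0)
    h, w = tree.image_size
    p0 = np.clip(mid - half * perp, [0, 0], [h - 1, w - 1])
    p1 = np.clip(mid + half * perp, [0, 0], [h - 1, w - 1])
    return (tuple(np.round(p0, 3)), tuple(np.round(p1, 3))), seg.radius


def split_counts(n: int, fractions) -> tuple:
    """Largest-remainder apportionment of n into len(fractions) parts."""
    fr = np.asarray(fractions, float)
    if not np.isclose(fr.sum(), 1.0):
        raise ValidationError("split fractions must sum to 1")
    raw = fr * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in order[:rem]:
        base[i] += 1
    return tuple(int(x) for x in base)


def generate_dataset(out_dir, n_pairs: int = 200, size=(120, 120),
                     base_seed: int = 0,
                     params: DegradationParams | None = None,
                     tree_params: BranchingConfig | None = None,
                     split_fractions=(0.8, 0.1, 0.1),
                     overwrite: bool = False) -> DatasetManifest:
    """Write ``n_pairs`` phantom pairs as 16-bit TIFFs plus manifest.json.

    Pair i uses tree seed ``base_seed + i`` and render seed
    ``base_seed + i + 1_000_000`` so trees and noise are independent.
    Regeneration with identical arguments is byte-identical.
    """
    import tifffile

    if n_pairs < 3:
        raise ValidationError("need n_pairs >= 3 (one per split)")
    params = params or DegradationParams()
    tree_params = tree_params or BranchingConfig()
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise Nir2aError(f"output directory {out_dir} is not empty; pass "
                         "overwrite=True to replace it")
    out_dir.mkdir(parents=True, exist_ok=True)

    n_train, n_val, n_test = split_counts(n_pairs, split_fractions)
    perm = np.random.default_rng(base_seed).permutation(n_pairs)
    labels = {}
    for rank, idx in enumerate(perm):
        pid = f"pair_{idx:04d}"
        labels[pid] = ("train" if rank < n_train else
                       "val" if rank < n_train + n_val else "test")

    entries = []
    for i in range(n_pairs):
        pid = f"pair_{i:04d}"
        tree = grow_vessel_tree(size, base_seed + i, tree_params)
        pair = render_pair(tree, params, base_seed + i + 1_000_000)
        line, radius = _profile_line_for(tree, params.psf_sigma_nir1)
        names = {}
        for tag, img in (("nir1", pair.nir1), ("nir2a", pair.nir2a)):
            name = f"{pid}_{tag}.tif"
            tifffile.imwrite(out_dir / name,
                             np.round(img * 65535).astype(np.uint16))
            names[tag] = name
        mask_name = f"{pid}_mask.tif"
        tifffile.imwrite(out_dir / mask_name,
                         (pair.vessel_mask.astype(np.uint16) * 65535))
        entries.append(ManifestEntry(pid, names["nir1"], names["nir2a"],
                                     mask_name, base_seed + i, line, radius))

    manifest = DatasetManifest(tuple(entries), labels, GENERATOR_VERSION,
                               base_seed, tuple(size), out_dir)
    payload = {
        "generator_version": GENERATOR_VERSION,
        "base_seed": base_seed,
        "size": list(size),
        "degradation": asdict(params),
        "branching": asdict(tree_params),
        "split_fractions": list(split_fractions),
        "split": labels,
        "entries": [{"pair_id": e.pair_id, "nir1": e.nir1,
                     "nir2a": e.nir2a, "mask": e.mask, "seed": e.seed,
                     "profile_line": [list(e.profile_line[0]),
                                      list(e.profile_line[1])],
                     "widest_radius": e.widest_radius}
                    for e in entries],
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True))
    return manifest


def default_pair(index: int, size=(120, 120),
                 params: DegradationParams | None = None,
                 base_seed: int = 0) -> PhantomPair:
    """Pair ``index`` of the default dataset: tree seed ``base_seed+index``,
    render seed ``base_seed+index+1_000_000`` (the generate_dataset
    convention, under which the degradation defaults were calibrated)."""
    tree = grow_vessel_tree(size, base_seed + index)
    return render_pair(tree, params, base_seed + index + 1_000_000)


def load_manifest(path) -> DatasetManifest:
    path = Path(path)
    payload = json.loads(path.read_text())
    entries = tuple(
        ManifestEntry(e["pair_id"], e["nir1"], e["nir2a"], e["mask"],
                      e["seed"],
                      (tuple(e["profile_line"][0]),
                       tuple(e["profile_line"][1])),
                      e["widest_radius"])
        for e in payload["entries"])
    return DatasetManifest(entries, payload["split"],
                           payload["generator_version"],
                           payload["base_seed"], tuple(payload["size"]),
                           path.parent)


def manifest_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
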