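"""Synthetic CT-colonography-like polyp phantoms.

Each phantom is a small HU-valued grid containing an air lumen
(about -1000 HU), a soft-tissue wall slab (about 40 HU), and a single
sessile polyp protruding from the wall into the lumen. Benign polyps are
rendered smooth and homogeneous; premalignant polyps receive a lobulated
surface (random angular bumps scaling the local radius) and intra-lesional
texture (a smoothed Gaussian random field added inside the mask). A single
``separability`` knob in [0, 1] scales both class-conditional differences:
at 0 the two classes are drawn from identical distributions, at 1 a trivial
intensity-heterogeneity feature separates them almost perfectly.

The generator is deliberately schematic — it emulates the *cohort
structure* of a CT colonography study (supine/prone duplicates of one
lesion, several polyps per patient, three size strata) rather than
radiologic realism.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .evaluate import max_3d_diameter, map_histopathology_to_class

__all__ = ["PhantomSpec", "PolypRecord", "generate_polyp_volume", "generate_cohort",
           "MANIFEST_COLUMNS"]

# HU model (means and noise standard deviations)
LUMEN_HU, LUMEN_SD = -1000.0, 30.0
WALL_HU, WALL_SD = 40.0, 20.0
# class-conditional increments at separability 1.0
_PREMALIGNANT_EXTRA_LOBULATION = 0.30
_PREMALIGNANT_EXTRA_TEXTURE_HU = 55.0

WALL_THICKNESS_MM = 6.0
_N_BUMPS = 8

MANIFEST_COLUMNS = ["patient_id", "polyp_id", "position", "histopathologic_category",
                    "class_label", "volume_path", "mask_path", "diameter_mm", "seed"]

# rough histology frequencies of a screening cohort, per class
_BENIGN_CATEGORIES = (["hyperplastic polyp"] * 90 + ["regular mucosa"] * 7
                      + ["lipomatous polyp"] * 3)
_PREMALIGNANT_CATEGORIES = (["tubular adenoma"] * 66 + ["tubulovillous adenoma"] * 19
                            + ["villous adenoma"] * 9 + ["serrated adenoma"] * 4
                            + ["adenocarcinoma"] * 2)


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one polyp phantom."""

    polyp_class: str = "benign"
    diameter_mm: float = 8.0
    lobulation: float = 0.05
    texture_sd: float = 5.0
    wall_offset_mm: float = 0.0
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    separability: float = 1.0
    size: int = 50

    def __post_init__(self):
        if self.polyp_class not in ("benign", "premalignant"):
            raise ValueError("polyp_class must be 'benign' or 'premalignant'")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.lobulation < 0 or self.texture_sd < 0:
            raise ValueError("lobulation and texture_sd must be non-negative")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")

    def effective_lobulation(self) -> float:
        if self.polyp_class == "premalignant":
            return self.lobulation + self.separability * _PREMALIGNANT_EXTRA_LOBULATION
        return self.lobulation

    def effective_texture_sd(self) -> float:
        if self.polyp_class == "premalignant":
            return self.texture_sd + self.separability * _PREMALIGNANT_EXTRA_TEXTURE_HU
        return self.texture_sd


@dataclass
class PolypRecord:
    """Metadata binding one rendered segmentation to its provenance."""

    patient_id: str
    polyp_id: str
    position: str
    histopathologic_category: str
    class_label: str
    diameter_mm: float
    seed: int
    volume_path: str = ""
    mask_path: str = ""


def _check_fits(spec: PhantomSpec) -> None:
    extent = min(s * spec.size for s in spec.voxel_spacing_mm)
    # polyp radius + lateral offset + margin must stay inside the half-grid
    needed = spec.diameter_mm * (0.5 + spec.effective_lobulation()) + abs(spec.wall_offset_mm) + 3.0
    if needed >= extent / 2.0:
        raise ValueError(
            f"diameter {spec.diameter_mm} mm does not fit a {spec.size}^3 grid at "
            f"spacing {spec.voxel_spacing_mm} (needs {needed:.1f} mm half-extent)")


def _bump_params(rng: np.random.Generator):
    """Random angular bump field parameters for the lobulated surface."""
    dirs = rng.normal(size=(_N_BUMPS, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    widths = rng.uniform(0.10, 0.35, _N_BUMPS)
    amps = rng.uniform(0.3, 1.0, _N_BUMPS)
    return dirs, widths, amps


def _rotate_xy(vec: np.ndarray, k: int) -> np.ndarray:
    """Rotate (…, 3) vectors by k*90 degrees about the z axis."""
    out = np.array(vec, dtype=float, copy=True)
    for _ in range(k % 4):
        x = out[..., 0].copy()
        out[..., 0] = -out[..., 1]
        out[..., 1] = x
    return out


def _render(spec: PhantomSpec, shape_rng: np.random.Generator,
            noise_rng: np.random.Generator, rot_k: int = 0):
    """Render one phantom; shape_rng drives geometry, noise_rng drives HU noise."""
    _check_fits(spec)
    S = spec.size
    sp = np.asarray(spec.voxel_spacing_mm, float)
    lob = spec.effective_lobulation()
    tex_sd = spec.effective_texture_sd()
    dirs, widths, amps = _bump_params(shape_rng)
    # per-polyp mild variation of the amplitudes
    amps = amps * shape_rng.uniform(0.8, 1.2)
    offset = np.array([spec.wall_offset_mm * np.cos(a := shape_rng.uniform(0, 2 * np.pi)),
                       spec.wall_offset_mm * np.sin(a), 0.0])

    def radius_with(dirset, units: np.ndarray) -> np.ndarray:
        s = np.zeros(units.shape[:-1])
        for d, w, a in zip(dirset, widths, amps):
            s += a * np.exp((units @ d - 1.0) / w)
        return s

    # Normalization constants for the bump field come from a fixed probe set
    # on the unrotated shape (rotation is an isometry), so the field is a
    # well-defined function of direction. The scale makes the maximal
    # antipodal chord equal diameter_mm.
    probe = shape_rng.normal(size=(400, 3))
    probe /= np.linalg.norm(probe, axis=1, keepdims=True)
    raw = np.concatenate([radius_with(dirs, probe), radius_with(dirs, -probe)])
    mu = raw.mean()
    denom = max(np.max(np.abs(raw - mu)), 1e-12)
    # half-voxel compensation: the mask diameter is measured between voxel
    # centres, which undershoots the continuous chord by about one spacing
    d_eff = spec.diameter_mm + float(np.mean(sp))
    r0 = d_eff / 2.0
    snorm_probe = (raw - mu) / denom
    rp = r0 * (1.0 + lob * snorm_probe[:400])
    rm = r0 * (1.0 + lob * snorm_probe[400:])
    scale = d_eff / float(np.max(rp + rm))

    if rot_k:
        dirs = _rotate_xy(dirs, rot_k)
        offset = _rotate_xy(offset[None], rot_k)[0]

    centre_vox = np.array([S / 2.0, S / 2.0, S / 2.0])
    centre_mm = centre_vox * sp + offset  # polyp base point on the wall plane
    z_wall = centre_mm[2]

    def radius(units: np.ndarray) -> np.ndarray:
        s = (radius_with(dirs, units) - mu) / denom
        return np.clip(s, -1.0, 1.0)

    idx = np.indices((S, S, S)).transpose(1, 2, 3, 0).astype(float)
    pos = idx * sp
    rel = pos - centre_mm
    dist = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        units = np.where(dist[..., None] > 0, rel / np.maximum(dist, 1e-9)[..., None], 0.0)
    rfield = scale * r0 * (1.0 + lob * radius(units))
    mask = (dist <= rfield) & (pos[..., 2] >= z_wall - 1e-9)
    mask[tuple(np.round(centre_vox).astype(int))] = True  # base voxel always inside

    wall = (pos[..., 2] < z_wall) & (pos[..., 2] >= z_wall - WALL_THICKNESS_MM)

    vol = np.full((S, S, S), LUMEN_HU, np.float32)
    vol += noise_rng.normal(0.0, LUMEN_SD, vol.shape).astype(np.float32)
    tissue_noise = noise_rng.normal(0.0, WALL_SD, vol.shape).astype(np.float32)
    tissue = wall | mask
    vol[tissue] = WALL_HU + tissue_noise[tissue]
    if tex_sd > 0:
        field = noise_rng.normal(size=vol.shape)
        field = ndimage.gaussian_filter(field, sigma=1.5)
        field /= max(field.std(), 1e-12)
        vol[mask] += (tex_sd * field[mask]).astype(np.float32)
    return vol, mask.astype(np.uint8)


def generate_polyp_volume(spec: PhantomSpec, seed: int):
    """Render one phantom subvolume deterministically from (spec, seed).

    Returns (volume HU grid, binary mask grid, PolypRecord). The mask's
    maximum 3-D diameter tracks ``spec.diameter_mm`` to within voxelization
    error (well inside +-20%).
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    ss = np.random.SeedSequence(seed)
    shape_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    vol, mask = _render(spec, shape_rng, noise_rng)
    cat_rng = np.random.default_rng(ss.spawn(1)[0])
    category = _draw_category(spec.polyp_class, cat_rng)
    rec = PolypRecord(
        patient_id="p0", polyp_id="p0_l0", position="supine",
        histopathologic_category=category, class_label=spec.polyp_class,
        diameter_mm=float(max_3d_diameter(mask, spec.voxel_spacing_mm)), seed=int(seed))
    return vol, mask, rec


def _draw_category(polyp_class: str, rng: np.random.Generator) -> str:
    pool = _BENIGN_CATEGORIES if polyp_class == "benign" else _PREMALIGNANT_CATEGORIES
    return pool[int(rng.integers(len(pool)))]


_STRATUM_RANGES = {"<=5": (3.4, 4.6), "6-9": (6.6, 8.4), ">=10": (10.5, 15.0)}


def _save_nifti(path: Path, arr: np.ndarray, spacing) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(spacing)
    img.header.set_data_dtype(arr.dtype)
    nib.save(img, str(path))


def generate_cohort(out_dir: str | Path, n_patients: int, class_prevalence: float = 0.5,
                    size_mix: tuple[float, float, float] = (0.15, 0.40, 0.45),
                    separability: float = 1.0, seed: int = 0,
                    polyps_per_patient: tuple[int, int] = (1, 3),
                    context: bool = True, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                    ) -> pd.DataFrame:
    """Write a synthetic cohort (volumes, masks, manifest CSV) to ``out_dir``.

    Every polyp is rendered in supine and prone positions sharing the same
    underlying shape but with independent noise and a 90-degree-multiple
    in-plane rotation of the lesion geometry. Class counts follow
    ``class_prevalence`` within integer rounding; size strata follow
    ``size_mix`` (fractions for <=5 / 6-9 / >=10 mm, summing to 1).
    With ``context=True`` volumes are written at 60^3 so training can crop
    randomly; masks are written at the canonical 50^3 centre crop alignment
    (60^3 as well, cropped consistently downstream).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not 0.0 < class_prevalence < 1.0:
        raise ValueError("class_prevalence must lie in (0, 1)")
    if abs(sum(size_mix) - 1.0) > 1e-9 or any(f < 0 for f in size_mix):
        raise ValueError("size_mix fractions must be non-negative and sum to 1")
    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    lo, hi = polyps_per_patient
    n_polyps_per_patient = rng.integers(lo, hi + 1, n_patients)
    n_polyps = int(n_polyps_per_patient.sum())

    # class assignment matching prevalence within rounding
    n_pre = int(round(class_prevalence * n_polyps))
    classes = np.array(["premalignant"] * n_pre + ["benign"] * (n_polyps - n_pre))
    rng.shuffle(classes)
    # size strata matching size_mix within rounding
    counts = [int(round(f * n_polyps)) for f in size_mix]
    while sum(counts) > n_polyps:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n_polyps:
        counts[int(np.argmax(size_mix))] += 1
    strata = sum(([s] * c for s, c in zip(_STRATUM_RANGES, counts)), [])
    rng.shuffle(strata)

    size = 60 if context else 50
    rows = []
    polyp_idx = 0
    for ip in range(n_patients):
        pid = f"pat{ip:03d}"
        for il in range(int(n_polyps_per_patient[ip])):
            lid = f"{pid}_l{il}"
            cls = str(classes[polyp_idx])
            lo_mm, hi_mm = _STRATUM_RANGES[strata[polyp_idx]]
            diameter = float(rng.uniform(lo_mm, hi_mm))
            category = _draw_category(cls, rng)
            spec = PhantomSpec(polyp_class=cls, diameter_mm=diameter,
                               separability=separability, size=size,
                               wall_offset_mm=float(rng.uniform(0.0, 2.0)),
                               voxel_spacing_mm=spacing)
            shape_seed = int(rng.integers(2 ** 31))
            rot_prone = int(rng.integers(1, 4))
            for position, rot_k in (("supine", 0), ("prone", rot_prone)):
                noise_seed = int(rng.integers(2 ** 31))
                shape_rng = np.random.default_rng(shape_seed)
                noise_rng = np.random.default_rng(noise_seed)
                vol, mask = _render(spec, shape_rng, noise_rng, rot_k=rot_k)
                vpath = out_dir / "volumes" / f"{lid}_{position}.nii.gz"
                mpath = out_dir / "masks" / f"{lid}_{position}_mask.nii.gz"
                _save_nifti(vpath, vol, spacing)
                _save_nifti(mpath, mask, spacing)
                rows.append({
                    "patient_id": pid, "polyp_id": lid, "position": position,
                    "histopathologic_category": category,
                    "class_label": map_histopathology_to_class(category),
                    "volume_path": str(vpath), "mask_path": str(mpath),
                    "diameter_mm": float(max_3d_diameter(mask, spacing)),
                    "seed": noise_seed,
                })
            polyp_idx += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
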