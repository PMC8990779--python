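"""Synthetic leaf occlusion and toy berry scenes.

Training the occluded-to-revealed translator needs aligned image pairs
of the same scene with and without leaves, which field campaigns cannot
deliver at scale.  The workaround implemented here starts from
non-occluded patches and *synthesises* the occluded partner: a leaf
template is rotated by one of eight canonical angles, overlaid opaquely
on the grayscale patch, and the berry mask is edited accordingly —
covered pixels become background while a thin closure band of berry-edge
pixels is laid where the leaf cuts through surviving berries, so
partially covered berries keep closed contours.

Because the original vineyard imagery is not redistributable, the module
also ships a toy scene generator (bright near-circular berries in
bunches on a darker background, interiors separated by edge rings) and a
toy leaf-template generator (lobed random polygons), so the full
pipeline runs end to end from nothing but a seed.  A loader accepts
user-supplied real leaf templates in the same texture + alpha format.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import masks

#: canonical leaf rotation angles, degrees
ROTATION_ANGLES = (-50, -30, -10, 0, 10, 30, 50, 70)


@dataclass
class LeafTemplate:
    """Grayscale leaf texture with a binary alpha footprint."""

    id: str
    texture: np.ndarray
    alpha: np.ndarray

    def __post_init__(self):
        self.texture = masks.as_gray(self.texture)
        self.alpha = np.asarray(self.alpha).astype(bool)
        if self.alpha.shape != self.texture.shape:
            raise ValueError("alpha and texture shapes differ")
        if not self.alpha.any():
            raise ValueError("leaf footprint is empty")


@dataclass(frozen=True)
class OcclusionSpec:
    """Everything needed to reproduce one synthetic leaf overlay."""

    leaf_id: str
    angle: float
    offset: tuple[int, int]       # (row, col) of the rotated footprint's top-left
    edge_closure_width: int = 3

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["offset"] = list(self.offset)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OcclusionSpec":
        return cls(leaf_id=d["leaf_id"], angle=d["angle"],
                   offset=tuple(d["offset"]),
                   edge_closure_width=d.get("edge_closure_width", 3))


def rotate_leaf(leaf: LeafTemplate, angle: float) -> LeafTemplate:
    """Rotate a leaf template; nearest-neighbour on alpha keeps it binary."""
    if angle == 0:
        return leaf
    tex = ndimage.rotate(leaf.texture.astype(np.float32), angle, reshape=True, order=1,
                         mode="constant", cval=0.0)
    alp = ndimage.rotate(leaf.alpha, angle, reshape=True, order=0,
                         mode="constant", cval=False)
    tex = np.clip(np.round(tex), 0, 255).astype(np.uint8)
    if not alp.any():  # numerically impossible for real leaves, guard anyway
        raise ValueError("rotation produced an empty footprint")
    return LeafTemplate(id=leaf.id, texture=tex, alpha=alp)


def _overlap_windows(patch_shape, leaf_shape, offset):
    """Slices of the patch and the leaf grids that overlap for this offset."""
    r0, c0 = offset
    pr0, pc0 = max(r0, 0), max(c0, 0)
    pr1 = min(r0 + leaf_shape[0], patch_shape[0])
    pc1 = min(c0 + leaf_shape[1], patch_shape[1])
    if pr1 <= pr0 or pc1 <= pc0:
        return None
    patch_win = (slice(pr0, pr1), slice(pc0, pc1))
    leaf_win = (slice(pr0 - r0, pr1 - r0), slice(pc0 - c0, pc1 - c0))
    return patch_win, leaf_win


def footprint_on_patch(patch_shape, leaf: LeafTemplate, spec: OcclusionSpec) -> np.ndarray:
    """Boolean grid over the patch marking the rotated leaf footprint."""
    rotated = rotate_leaf(leaf, spec.angle)
    grid = np.zeros(patch_shape, dtype=bool)
    wins = _overlap_windows(patch_shape, rotated.alpha.shape, spec.offset)
    if wins is None:
        raise ValueError("leaf footprint lies entirely off the patch")
    patch_win, leaf_win = wins
    grid[patch_win] = rotated.alpha[leaf_win]
    if not grid.any():
        raise ValueError("leaf footprint lies entirely off the patch")
    return grid


def apply_leaf_to_gray(gray, leaf: LeafTemplate, spec: OcclusionSpec) -> np.ndarray:
    """Opaquely overlay the rotated leaf texture; pixels outside stay untouched."""
    g = masks.as_gray(gray)
    rotated = rotate_leaf(leaf, spec.angle)
    wins = _overlap_windows(g.shape, rotated.alpha.shape, spec.offset)
    if wins is None:
        raise ValueError("leaf footprint lies entirely off the patch")
    patch_win, leaf_win = wins
    inside = rotated.alpha[leaf_win]
    if not inside.any():
        raise ValueError("leaf footprint lies entirely off the patch")
    out = g.copy()
    out[patch_win][inside] = rotated.texture[leaf_win][inside]
    return out


def derive_occluded_mask(mask_non, leaf: LeafTemplate, spec: OcclusionSpec) -> np.ndarray:
    """Edit the berry mask to match a leaf overlay.

    Covered pixels become background; where the leaf abuts surviving
    berry pixels, a closure band of width ``edge_closure_width`` becomes
    berry-edge so cut berries keep closed contours.  Pixels outside the
    footprint are returned bit-identical.
    """
    m = masks.as_mask(mask_non)
    fp = footprint_on_patch(m.shape, leaf, spec)
    out = m.copy()
    out[fp] = masks.BACKGROUND
    surviving_berry = (m == masks.BERRY) & ~fp
    if spec.edge_closure_width > 0 and surviving_berry.any():
        band = ndimage.binary_dilation(
            surviving_berry, structure=np.ones((3, 3), bool),
            iterations=spec.edge_closure_width)
        out[band & fp] = masks.BERRY_EDGE
    return out


def reconstruct_generated_input(generated_non, leaf: LeafTemplate,
                                spec: OcclusionSpec) -> np.ndarray:
    """Re-occlude a generated non-occluded mask with the leaf that made its input.

    By construction the result agrees with the original occluded input
    everywhere inside the leaf footprint region, so comparing it with
    that input isolates how faithfully the visible pixels were carried
    through the translation.
    """
    return derive_occluded_mask(generated_non, leaf, spec)


def patch_admissible(mask_non, mask_occ, threshold: float = 1.0 / 24.0,
                     literal: bool = False) -> bool:
    """Decide whether a synthetic pair carries enough berry signal to keep.

    Default reading: the non-occluded mask's *non-background* fraction
    must strictly exceed ``threshold`` and the occluded mask must retain
    at least one non-background pixel.  ``literal=True`` instead requires
    the background fraction to exceed the threshold.
    """
    mn, mo = masks.as_mask(mask_non), masks.as_mask(mask_occ)
    if mn.shape != mo.shape:
        raise ValueError("mask shapes differ")
    bg_frac = np.count_nonzero(mn == masks.BACKGROUND) / mn.size
    frac = bg_frac if literal else 1.0 - bg_frac
    return bool(frac > threshold and np.any(mo != masks.BACKGROUND))


# ---------------------------------------------------------------------------
# toy data generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToySceneSpec:
    """Parameters of one synthetic berry scene.

    Defaults render bunches of well-separated bright berries whose
    interiors comfortably pass every counting filter, so planted counts
    are exactly recoverable on noiseless scenes.
    """

    height: int = 64
    width: int = 64
    n_bunches: tuple[int, int] = (1, 1)
    berries_per_bunch: tuple[int, int] = (4, 8)
    berry_radius: tuple[int, int] = (6, 9)
    background_intensity: tuple[int, int] = (20, 60)
    berry_intensity: tuple[int, int] = (170, 235)
    edge_ring_width: int = 2
    noise_sd: float = 4.0
    strict_packing: bool = False


def generate_toy_scene(spec: ToySceneSpec, rng) -> tuple[np.ndarray, np.ndarray, int]:
    """Render one toy scene: (grayscale patch, berry mask, planted count).

    Berries are placed by rejection sampling with non-overlapping outer
    disks.  When the requested berries do not fit, the scene is rendered
    with as many as fit (``strict_packing=True`` raises instead).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    h, w = spec.height, spec.width
    bg = rng.integers(spec.background_intensity[0], spec.background_intensity[1] + 1)
    gray = np.clip(bg + rng.normal(0.0, spec.noise_sd, (h, w)), 0, 255)
    mask = np.zeros((h, w), dtype=np.uint8)

    rmin, rmax = spec.berry_radius
    placed: list[tuple[int, int, int]] = []
    n_bunches = int(rng.integers(spec.n_bunches[0], spec.n_bunches[1] + 1))
    requested = 0
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_bunches):
        n_berries = int(rng.integers(spec.berries_per_bunch[0],
                                     spec.berries_per_bunch[1] + 1))
        requested += n_berries
        bc = (rng.uniform(rmax, h - rmax), rng.uniform(rmax, w - rmax))
        for _ in range(n_berries):
            r = int(rng.integers(rmin, rmax + 1))
            ok = False
            for _attempt in range(300):
                row = bc[0] + rng.normal(0.0, 1.8 * rmax)
                col = bc[1] + rng.normal(0.0, 1.8 * rmax)
                if not (r <= row < h - r and r <= col < w - r):
                    continue
                if all((row - pr) ** 2 + (col - pc) ** 2 >= (r + prad + 1) ** 2
                       for pr, pc, prad in placed):
                    ok = True
                    break
            if not ok:
                continue
            placed.append((row, col, r))
            d2 = (yy - row) ** 2 + (xx - col) ** 2
            outer = d2 <= r ** 2
            inner = d2 <= (r - spec.edge_ring_width) ** 2
            mask[outer & ~inner] = masks.BERRY_EDGE
            mask[inner] = masks.BERRY
            intensity = rng.integers(spec.berry_intensity[0],
                                     spec.berry_intensity[1] + 1)
            # darker rim plus mild noise keeps the gray channel informative
            gray[outer] = np.clip(
                intensity - 40.0 * (d2[outer] / max(r * r, 1)) ** 2
                + rng.normal(0.0, spec.noise_sd, int(outer.sum())), 0, 255)
    if spec.strict_packing and len(placed) < requested:
        raise ValueError(
            f"could not pack {requested} berries; placed only {len(placed)}")
    return gray.astype(np.uint8), mask, len(placed)


def make_toy_leaf(leaf_id: str, rng, size: int = 36, n_lobes: int = 7) -> LeafTemplate:
    """Random lobed near-convex polygon standing in for a vine leaf."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    theta = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
    base = size / 2.0 - 2.0
    phase = rng.uniform(0, 2 * np.pi)
    radius = base * (0.72 + 0.22 * np.cos(n_lobes * theta + phase)
                     + 0.06 * np.sin(2 * theta + rng.uniform(0, 2 * np.pi)))
    rows = size / 2.0 + radius * np.sin(theta)
    cols = size / 2.0 + radius * np.cos(theta) * rng.uniform(0.8, 1.15)
    from skimage.draw import polygon

    rr, cc = polygon(rows, cols, shape=(size, size))
    alpha = np.zeros((size, size), dtype=bool)
    alpha[rr, cc] = True
    # leaf texture: mid-gray with venation-like ripples, distinct from berries
    yy, xx = np.mgrid[0:size, 0:size]
    tex = (95 + 18 * np.sin(xx / 2.5 + phase) * np.cos(yy / 3.5)
           + rng.normal(0, 4, (size, size)))
    texture = np.clip(tex, 0, 255).astype(np.uint8)
    texture[~alpha] = 0
    return LeafTemplate(id=leaf_id, texture=texture, alpha=alpha)


def make_toy_leaves(n: int = 24, rng=0, size: int = 36) -> list[LeafTemplate]:
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return [make_toy_leaf(f"leaf{i:02d}", rng, size=size) for i in range(n)]


def save_leaves(leaves: list[LeafTemplate], leafdir) -> None:
    """Write templates as ``<leafdir>/<id>_{texture,alpha}.png``."""
    leafdir = Path(leafdir)
    leafdir.mkdir(parents=True, exist_ok=True)
    for leaf in leaves:
        masks.write_image(leafdir / f"{leaf.id}_texture.png", leaf.texture)
        masks.write_image(leafdir / f"{leaf.id}_alpha.png",
                          leaf.alpha.astype(np.uint8) * 255)


def load_leaves(leafdir) -> list[LeafTemplate]:
    """Load templates saved by :func:`save_leaves` (or real ones in that format)."""
    leafdir = Path(leafdir)
    leaves = []
    for tex_path in sorted(leafdir.glob("*_texture.png")):
        leaf_id = tex_path.name[: -len("_texture.png")]
        texture = masks.read_image(tex_path)
        alpha = masks.read_image(leafdir / f"{leaf_id}_alpha.png") > 127
        leaves.append(LeafTemplate(id=leaf_id, texture=texture, alpha=alpha))
    if not leaves:
        raise ValueError(f"no leaf templates found under {leafdir}")
    return leaves


# ---------------------------------------------------------------------------
# paired dataset construction
# ---------------------------------------------------------------------------

@dataclass
class PairRecord:
    pair_id: str
    split: str                    # "train" | "test"
    spec: OcclusionSpec

    def to_dict(self) -> dict:
        return {"pair_id": self.pair_id, "split": self.split,
                "spec": self.spec.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "PairRecord":
        return cls(pair_id=d["pair_id"], split=d["split"],
                   spec=OcclusionSpec.from_dict(d["spec"]))


@dataclass
class DatasetManifest:
    records: list[PairRecord]
    train_leaves: list[str]
    test_leaves: list[str]
    seed: int
    root: str = ""

    def split_records(self, split: str) -> list[PairRecord]:
        return [r for r in self.records if r.split == split]

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "train_leaves": self.train_leaves,
            "test_leaves": self.test_leaves,
            "records": [r.to_dict() for r in self.records],
        }, indent=2, sort_keys=True)

    def save(self, root) -> None:
        Path(root, "manifest.json").write_text(self.to_json())

    @classmethod
    def load(cls, root) -> "DatasetManifest":
        d = json.loads(Path(root, "manifest.json").read_text())
        return cls(records=[PairRecord.from_dict(r) for r in d["records"]],
                   train_leaves=d["train_leaves"], test_leaves=d["test_leaves"],
                   seed=d["seed"], root=str(root))


def _pair_paths(root, split, pair_id):
    root = Path(root)
    return {
        "occ_gray": root / split / "occ" / "gray" / f"{pair_id}.png",
        "occ_mask": root / split / "occ" / "mask" / f"{pair_id}.png",
        "non_gray": root / split / "non" / "gray" / f"{pair_id}.png",
        "non_mask": root / split / "non" / "mask" / f"{pair_id}.png",
    }


def build_dataset(patches, leaves, out_dir, *, n_train_leaves: int = 18,
                  n_test_leaves: int = 6, train_multiplicity: int = 9,
                  test_multiplicity: int = 3, train_fraction: float = 0.8,
                  admissibility_threshold: float = 1.0 / 24.0,
                  literal_admissibility: bool = False,
                  edge_closure_width: int = 3,
                  min_on_patch_fraction: float = 0.25,
                  angles=ROTATION_ANGLES, seed: int = 0) -> DatasetManifest:
    """Build a paired occluded/non-occluded dataset by synthetic leaf overlay.

    ``patches`` is a sequence of ``(gray, mask)`` non-occluded patches.
    Leaves are partitioned disjointly into a training set (default 18)
    and a test set (default 6); each training patch receives up to 9
    occluded versions and each test patch up to 3, keeping only pairs
    that pass the admissibility rule.  Everything is reproducible from
    ``seed`` and the layout on disk is
    ``<root>/{train,test}/{occ,non}/{gray,mask}/<pair_id>.png`` plus a
    ``manifest.json``.
    """
    if not leaves:
        raise ValueError("need at least one leaf template")
    if len(leaves) < n_train_leaves + n_test_leaves:
        raise ValueError(
            f"need {n_train_leaves + n_test_leaves} leaves, got {len(leaves)}")
    if not patches:
        raise ValueError("need at least one non-occluded patch")
    rng = np.random.default_rng(seed)
    leaf_order = rng.permutation(len(leaves))
    train_leaves = [leaves[i] for i in leaf_order[:n_train_leaves]]
    test_leaves = [leaves[i] for i in leaf_order[n_train_leaves:
                                                 n_train_leaves + n_test_leaves]]
    patch_order = rng.permutation(len(patches))
    n_train_patches = max(1, int(round(train_fraction * len(patches))))
    if len(patches) > 1:
        n_train_patches = min(n_train_patches, len(patches) - 1)
    split_of = {int(i): ("train" if k < n_train_patches else "test")
                for k, i in enumerate(patch_order)}

    out_dir = Path(out_dir)
    records: list[PairRecord] = []
    for idx in range(len(patches)):
        gray, mask = patches[idx]
        gray, mask = masks.as_gray(gray), masks.as_mask(mask)
        split = split_of[idx]
        pool = train_leaves if split == "train" else test_leaves
        mult = train_multiplicity if split == "train" else test_multiplicity
        for k in range(mult):
            leaf = pool[int(rng.integers(len(pool)))]
            angle = float(angles[int(rng.integers(len(angles)))])
            spec = _sample_placement(mask.shape, leaf, angle, rng,
                                     edge_closure_width, min_on_patch_fraction)
            if spec is None:
                continue
            mask_occ = derive_occluded_mask(mask, leaf, spec)
            if not patch_admissible(mask, mask_occ, admissibility_threshold,
                                    literal=literal_admissibility):
                continue
            gray_occ = apply_leaf_to_gray(gray, leaf, spec)
            pair_id = f"p{idx:04d}_{k}"
            paths = _pair_paths(out_dir, split, pair_id)
            masks.write_image(paths["occ_gray"], gray_occ)
            masks.write_image(paths["occ_mask"], mask_occ)
            masks.write_image(paths["non_gray"], gray)
            masks.write_image(paths["non_mask"], mask)
            records.append(PairRecord(pair_id=pair_id, split=split, spec=spec))

    manifest = DatasetManifest(
        records=records,
        train_leaves=[leaf.id for leaf in train_leaves],
        test_leaves=[leaf.id for leaf in test_leaves],
        seed=seed, root=str(out_dir))
    manifest.save(out_dir)
    return manifest


def _sample_placement(patch_shape, leaf, angle, rng, edge_closure_width,
                      min_on_patch_fraction, max_tries: int = 50):
    """Uniform placement keeping at least a fraction of the footprint on-patch."""
    rotated = rotate_leaf(leaf, angle)
    lh, lw = rotated.alpha.shape
    total = int(rotated.alpha.sum())
    for _ in range(max_tries):
        off = (int(rng.integers(-lh + 1, patch_shape[0])),
               int(rng.integers(-lw + 1, patch_shape[1])))
        spec = OcclusionSpec(leaf_id=leaf.id, angle=angle, offset=off,
                             edge_closure_width=edge_closure_width)
        wins = _overlap_windows(patch_shape, rotated.alpha.shape, off)
        if wins is None:
            continue
        on_patch = int(rotated.alpha[wins[1]].sum())
        if on_patch >= min_on_patch_fraction * total:
            return spec
    return None


def load_pairs(manifest: DatasetManifest, split: str):
    """Yield ``(record, occ_gray, occ_mask, non_gray, non_mask)`` for a split."""
    for rec in manifest.split_records(split):
        paths = _pair_paths(manifest.root, rec.split, rec.pair_id)
        yield (rec,
               masks.read_image(paths["occ_gray"]),
               masks.read_image(paths["occ_mask"]),
               masks.read_image(paths["non_gray"]),
               masks.read_image(paths["non_mask"]))
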