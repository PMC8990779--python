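"""End-to-end toy benchmark: generate, occlude, train, translate, count.

This is the package's counting experiment run entirely on
synthetic data: toy berry scenes stand in for defoliated vineyard
patches, toy leaf templates occlude them, a small translator is trained
on the paired data, and counting on the generated outputs is compared
against counting on the occluded inputs relative to the reference
counts.  The expectation under the method is that translation moves the
counts toward the reference — higher identity-line R^2 and a smaller
mean absolute relative deviation than the occluded inputs give.

Problem sizes (about 200 training pairs of 64x64 patches, a base-16
three-level generator, 30 epochs) are chosen so the whole run completes
in minutes on one CPU while leaving the occlusion signal clearly
measurable.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import evaluation, occlusion, pix2pix


def run_toy_benchmark(seed: int = 0, workdir=None, n_patches: int = 30,
                      epochs: int = 30, channels: str = "GB",
                      out_dir=None) -> dict:
    """Run the full occlusion-revealing pipeline on seeded toy data.

    Returns the evaluation summary extended with the training history
    and dataset sizes.  ``workdir`` holds the intermediate dataset (a
    temporary directory by default); ``out_dir`` optionally receives the
    per-patch evaluation artifacts.
    """
    master = np.random.default_rng(seed)
    leaf_seed, scene_seed, split_seed, model_seed = \
        (int(s) for s in master.integers(0, 2 ** 31 - 1, size=4))

    leaves = occlusion.make_toy_leaves(24, leaf_seed)
    scene_rng = np.random.default_rng(scene_seed)
    spec = occlusion.ToySceneSpec()
    patches = []
    for _ in range(n_patches):
        gray, mask, _ = occlusion.generate_toy_scene(spec, scene_rng)
        patches.append((gray, mask))

    with tempfile.TemporaryDirectory() as tmp:
        root = Path(workdir) if workdir is not None else Path(tmp) / "dataset"
        manifest = occlusion.build_dataset(patches, leaves, root,
                                           seed=split_seed)
        pairs = [
            (pix2pix.stack_channels(og, om, channels),
             pix2pix.stack_channels(ng, nm, channels))
            for _, og, om, ng, nm in occlusion.load_pairs(manifest, "train")]
        model = pix2pix.Pix2PixTranslator.toy(seed=model_seed, epochs=epochs,
                                              channels=channels)
        model.fit(pairs)
        report = evaluation.run_experiments(manifest, model, leaves,
                                            out_dir=out_dir)

    result = dict(report.summary)
    result["n_train_pairs"] = len(pairs)
    result["l1_first_epoch"] = model.history_[0]["l1"]
    result["l1_last_epoch"] = model.history_[-1]["l1"]
    result["history"] = model.history_
    return result


def recover_filter_cutoffs() -> dict:
    """Recover the counting filter cut-offs by sweeping synthetic components.

    Sweeps round components through increasing areas and elongated
    components through increasing axis ratios, and reports the smallest
    retained value of each — the operative size and shape thresholds of
    the counting filters.
    """
    import math

    from . import counting

    def round_component(area):
        d = 2.0 * math.sqrt(area / math.pi)
        return counting.BerryComponent(label=1,
                                       pixels=np.zeros((area, 2), dtype=int),
                                       area=area, centroid=(0.0, 0.0),
                                       major_axis=d, minor_axis=d,
                                       edge_surround=1.0)

    def ratio_component(ratio, major=50.0):
        minor = ratio * major
        area = int(math.ceil(math.pi * ((major + minor) / 4.0) ** 2))
        return counting.BerryComponent(label=1,
                                       pixels=np.zeros((area, 2), dtype=int),
                                       area=area, centroid=(0.0, 0.0),
                                       major_axis=major, minor_axis=minor,
                                       edge_surround=1.0)

    min_area = min(a for a in range(1, 200)
                   if counting.filter_components([round_component(a)]).count)
    ratios = np.round(np.arange(0.01, 1.001, 0.01), 2)
    min_ratio = min(float(r) for r in ratios
                    if counting.filter_components([ratio_component(r)]).count)
    return {"size_cutoff": min_area, "axis_ratio_cutoff": min_ratio}
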