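"""Experiment harness: counting comparison, R^2, histograms, generation maps.

A generated scene cannot be judged pixel-by-pixel against the hidden
truth — the method only promises a *plausible* arrangement of berries —
so evaluation combines several complementary views:

* reconstruction fidelity in the occluded domain (re-occlude the
  generated output with the very leaf that produced the input and
  compare with that input; the two must agree on the visible pixels),
* mask similarity in the non-occluded domain (correlation, per-class
  and binary IoU, generation maps),
* berry statistics (per-berry area and equivalent-circle diameter), and
* counting accuracy (counts on occluded inputs and on generated outputs
  against the reference count, summarised by identity-line R^2 and by
  the distribution of relative count deviations).

Every aggregate is recomputable from the per-patch artifacts the runner
writes to disk; there is no hidden state.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import counting, masks, occlusion, pix2pix


def r_squared(predicted, reference, against: str = "identity") -> float:
    """Coefficient of determination of predictions against references.

    With ``against="identity"`` (the default) residuals are taken from
    the identity line, so perfect prediction gives 1 and the value can
    go negative; ``against="ols"`` instead scores an ordinary
    least-squares fit of predicted on reference.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError("predicted and reference must be equal-length 1-D")
    if len(p) < 2:
        raise ValueError("need at least two points")
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("reference variance is zero")
    if against == "identity":
        resid = p - r
    elif against == "ols":
        coef = np.polyfit(r, p, 1)
        resid = p - np.polyval(coef, r)
    else:
        raise ValueError(f"unknown mode {against!r}")
    return 1.0 - float(np.sum(resid ** 2)) / ss_tot


@dataclass
class CountComparison:
    """Per-patch counts plus aggregate identity-line R^2 values."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_counts(cls, reference, occluded, generated, pair_ids=None):
        ref = np.asarray(reference, dtype=int)
        occ = np.asarray(occluded, dtype=int)
        gen = np.asarray(generated, dtype=int)
        if not (len(ref) == len(occ) == len(gen)):
            raise ValueError("count vectors differ in length")
        ids = pair_ids if pair_ids is not None else [str(i) for i in range(len(ref))]
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_occ = np.where(ref > 0, (occ - ref) / np.where(ref > 0, ref, 1), np.nan)
            dev_gen = np.where(ref > 0, (gen - ref) / np.where(ref > 0, ref, 1), np.nan)
        return cls(records=pd.DataFrame({
            "pair_id": ids, "reference": ref, "occluded": occ, "generated": gen,
            "rel_dev_occluded": dev_occ, "rel_dev_generated": dev_gen}))

    def r2(self, which: str, against: str = "identity") -> float:
        return r_squared(self.records[which], self.records["reference"],
                         against=against)

    def mean_abs_deviation(self, which: str) -> float:
        col = self.records[f"rel_dev_{which}"].dropna()
        return float(col.abs().mean())


def relative_deviation_histogram(comparison: CountComparison,
                                 bin_width: float = 0.02) -> pd.DataFrame:
    """Normalised histograms of relative count deviation, one series per
    domain (occluded inputs vs generated outputs).

    Patches with a zero reference count carry no relative deviation and
    are excluded with a warning.  Negative bins mean undercounting.
    """
    df = comparison.records
    n_zero = int((df["reference"] == 0).sum())
    if n_zero:
        warnings.warn(f"excluding {n_zero} patches with zero reference count")
    valid = df[df["reference"] > 0]
    devs = {"occluded": valid["rel_dev_occluded"].to_numpy(),
            "generated": valid["rel_dev_generated"].to_numpy()}
    lo = min((d.min() for d in devs.values() if len(d)), default=0.0)
    hi = max((d.max() for d in devs.values() if len(d)), default=0.0)
    left = np.floor(lo / bin_width) * bin_width
    right = np.ceil(hi / bin_width) * bin_width + bin_width / 2
    edges = np.arange(left, right + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([-bin_width / 2, bin_width / 2])
    rows = []
    for series, d in devs.items():
        hist, _ = np.histogram(d, bins=edges)
        frac = hist / hist.sum() if hist.sum() else hist.astype(float)
        for b, (e0, f) in enumerate(zip(edges[:-1], frac)):
            rows.append({"series": series, "bin_left": e0,
                         "bin_right": e0 + bin_width, "fraction": f})
    return pd.DataFrame(rows)


def correlation_histogram(values, bin_width: float = 0.01) -> pd.DataFrame:
    """Normalised histogram of correlation values on [-1, 1]."""
    v = np.asarray(values, dtype=float)
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    hist, _ = np.histogram(np.clip(v, -1.0, 1.0 - 1e-12), bins=edges)
    frac = hist / hist.sum() if hist.sum() else hist.astype(float)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "fraction": frac})


@dataclass
class ExperimentReport:
    per_patch: pd.DataFrame
    count_comparison: CountComparison
    summary: dict
    out_dir: str | None = None


def run_experiments(manifest: occlusion.DatasetManifest,
                    model: pix2pix.Pix2PixTranslator,
                    leaves: list[occlusion.LeafTemplate],
                    out_dir=None,
                    counter: counting.BerryCounter | None = None,
                    correlation_mode: str = "labels",
                    deviation_bin_width: float = 0.02,
                    correlation_bin_width: float = 0.01,
                    split: str = "test") -> ExperimentReport:
    """Run the full evaluation battery on one split of a paired dataset.

    Per pair: translate the occluded stack, post-process the generated
    mask, re-occlude it to check the occluded domain, compute
    correlations, IoUs, generation maps and berry counts, then aggregate.
    When ``out_dir`` is given, per-patch PNGs, metric CSVs, histogram
    CSVs and ``report.json`` are written so every aggregate can be
    recomputed from disk.
    """
    counter = counter or counting.BerryCounter()
    leaf_by_id = {leaf.id: leaf for leaf in leaves}
    records = list(occlusion.load_pairs(manifest, split))
    if not records:
        raise ValueError(f"no {split!r} records in manifest")
    out_dir = Path(out_dir) if out_dir is not None else None

    rows = []
    ref_counts, occ_counts, gen_counts, pair_ids = [], [], [], []
    sizes = []
    for rec, occ_gray, occ_mask, non_gray, non_mask in records:
        leaf = leaf_by_id[rec.spec.leaf_id]
        stack = pix2pix.stack_channels(occ_gray, occ_mask, model.channels)
        gen_gray, gen_mask = model.translate(stack)
        gen_occ_mask = occlusion.reconstruct_generated_input(gen_mask, leaf, rec.spec)

        row = {"pair_id": rec.pair_id}
        row["corr_occ"] = _safe_corr(occ_mask, gen_occ_mask, correlation_mode)
        row["corr_non"] = _safe_corr(non_mask, gen_mask, correlation_mode)
        for cls in masks.CLASS_VALUES:
            row[f"iou_{masks.CLASS_NAMES[cls]}"] = masks.iou(non_mask, gen_mask, cls)
        row["iou_binary"] = masks.iou(masks.merge_to_binary(non_mask),
                                      masks.merge_to_binary(gen_mask), masks.BERRY)
        ref_res = counter.count(non_mask)
        occ_res = counter.count(occ_mask)
        gen_res = counter.count(gen_mask)
        row["count_reference"] = ref_res.count
        row["count_occluded"] = occ_res.count
        row["count_generated"] = gen_res.count
        rows.append(row)
        ref_counts.append(ref_res.count)
        occ_counts.append(occ_res.count)
        gen_counts.append(gen_res.count)
        pair_ids.append(rec.pair_id)
        for area, diameter in counting.berry_size_stats(gen_res):
            sizes.append({"pair_id": rec.pair_id, "source": "generated",
                          "area": area, "diameter": diameter})
        for area, diameter in counting.berry_size_stats(ref_res):
            sizes.append({"pair_id": rec.pair_id, "source": "reference",
                          "area": area, "diameter": diameter})

        if out_dir is not None:
            gal = out_dir / "patches" / rec.pair_id
            masks.write_image(gal / "generated_mask.png", gen_mask)
            if gen_gray is not None:
                masks.write_image(gal / "generated_gray.png", gen_gray)
            masks.write_image(gal / "reconstructed_occluded_mask.png", gen_occ_mask)
            masks.write_generation_map(
                gal / "genmap_occluded.png",
                masks.generation_map(occ_mask, gen_occ_mask))
            masks.write_generation_map(
                gal / "genmap_non_occluded.png",
                masks.generation_map(non_mask, gen_mask))
            masks.write_generation_map(
                gal / "genmap_binary.png",
                masks.generation_map(non_mask, gen_mask, binary=True))

    per_patch = pd.DataFrame(rows)
    comparison = CountComparison.from_counts(ref_counts, occ_counts, gen_counts,
                                             pair_ids)
    dev_hist = relative_deviation_histogram(comparison, deviation_bin_width)
    corr_hist_non = correlation_histogram(per_patch["corr_non"].dropna(),
                                          correlation_bin_width)
    corr_hist_occ = correlation_histogram(per_patch["corr_occ"].dropna(),
                                          correlation_bin_width)
    size_df = pd.DataFrame(sizes)

    summary = {
        "n_pairs": len(per_patch),
        "mean_corr_occ": float(per_patch["corr_occ"].mean()),
        "mean_corr_non": float(per_patch["corr_non"].mean()),
        "mean_iou_berry": float(per_patch["iou_berry"].mean()),
        "mean_iou_binary": float(per_patch["iou_binary"].mean()),
        "r2_occluded": _safe_r2(comparison, "occluded"),
        "r2_generated": _safe_r2(comparison, "generated"),
        "mean_abs_rel_dev_occluded": comparison.mean_abs_deviation("occluded"),
        "mean_abs_rel_dev_generated": comparison.mean_abs_deviation("generated"),
    }

    if out_dir is not None:
        per_patch.to_csv(out_dir / "metrics.csv", index=False)
        comparison.records.to_csv(out_dir / "counts.csv", index=False)
        dev_hist.to_csv(out_dir / "relative_deviation_hist.csv", index=False)
        corr_hist_non.to_csv(out_dir / "correlation_hist_non.csv", index=False)
        corr_hist_occ.to_csv(out_dir / "correlation_hist_occ.csv", index=False)
        size_df.to_csv(out_dir / "berry_sizes.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(summary, indent=2))

    return ExperimentReport(per_patch=per_patch, count_comparison=comparison,
                            summary=summary,
                            out_dir=str(out_dir) if out_dir else None)


def _safe_corr(a, b, mode):
    try:
        return masks.pearson_correlation(a, b, mode=mode)
    except ValueError:
        return float("nan")


def _safe_r2(comparison, which):
    """NaN when R^2 is undefined (fewer than 2 pairs or constant reference)."""
    try:
        return comparison.r2(which)
    except ValueError:
        return float("nan")
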