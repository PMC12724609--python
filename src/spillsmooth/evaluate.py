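"""Marker-separability and batch-mixing metrics, plus the simulation
sweep harnesses.

AUROC is the probability that a randomly chosen positive cell scores
higher than a randomly chosen negative one, computed by Mann-Whitney
pair counting. ``tie_policy='half'`` gives tied pairs half credit (the
rank-based convention); ``'strict'`` counts only strictly greater pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors

from .model import IntensityImage, LabelMask
from .aggregate import mean_aggregate
from .gz import NeighborhoodSpec, box_blur, gz_normalize
from .resample import RATIParams, rati
from .sci import SCIParams, apply_sci
from .simulate import ChannelSpec, SimulationConfig, simulate_dataset

__all__ = [
    "auroc",
    "f1_max",
    "population_distance",
    "inverse_simpson_index",
    "resolution_sweep",
    "method_comparison",
]


def _check_classes(scores, labels):
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1D arrays of equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return s, y, n_pos, n_neg


def auroc(scores, labels, tie_policy: str = "half") -> float:
    """Pair-counting AUROC.

    Equivalent to the normalized Mann-Whitney U statistic: average ranks
    give tied positive-negative pairs half credit; ``tie_policy='strict'``
    scores them 0 (the plain ``s⁺ > s⁻`` indicator).
    """
    if tie_policy not in ("half", "strict"):
        raise ValueError("tie_policy must be 'half' or 'strict'")
    s, y, n_pos, n_neg = _check_classes(scores, labels)
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    if tie_policy == "strict":
        # remove the half credit granted to cross-class ties
        vals, inv = np.unique(s, return_inverse=True)
        pos_counts = np.bincount(inv[y == 1], minlength=len(vals))
        neg_counts = np.bincount(inv[y == 0], minlength=len(vals))
        tie_pairs = float(np.sum(pos_counts * neg_counts))
        auc -= 0.5 * tie_pairs / (n_pos * n_neg)
    return float(auc)


def f1_max(scores, labels) -> tuple[float, float, float, float]:
    """Best F1 over all thresholds (positive iff ``s ≥ t``).

    Candidate thresholds are the midpoints between consecutive distinct
    scores plus ±∞; ties in F1 resolve to the lowest threshold. Returns
    ``(f1, threshold, precision, recall)``; F1 with TP = 0 is 0."""
    s, y, n_pos, _ = _check_classes(scores, labels)
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    best = (-1.0, np.inf, 0.0, 0.0)
    for t in thresholds:
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = n_pos - tp
        if tp == 0:
            f1, prec, rec = 0.0, 0.0, 0.0
        else:
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            f1 = 2 * prec * rec / (prec + rec)
        if f1 > best[0] or (f1 == best[0] and t < best[1]):
            best = (f1, float(t), prec, rec)
    return best


def population_distance(scores, labels, standardized: bool = False) -> float:
    """Absolute difference between positive and negative mean scores;
    optionally divided by the pooled (ddof=1) standard deviation."""
    s, y, n_pos, n_neg = _check_classes(scores, labels)
    pos, neg = s[y == 1], s[y == 0]
    d = abs(float(pos.mean() - neg.mean()))
    if standardized:
        num = 0.0
        if n_pos > 1:
            num += (n_pos - 1) * pos.var(ddof=1)
        if n_neg > 1:
            num += (n_neg - 1) * neg.var(ddof=1)
        dof = n_pos + n_neg - 2
        pooled = np.sqrt(num / dof) if dof > 0 else 0.0
        if pooled == 0:
            raise ValueError("zero pooled sd with standardized=True")
        d /= pooled
    return d


def inverse_simpson_index(
    features, group_labels, k: int = 100, per_group: bool = False
):
    """Mean kNN inverse Simpson index — the effective number of groups
    among each cell's k nearest (Euclidean) neighbours, self excluded.

    1 means every neighbourhood is a single group (no mixing); the number
    of groups means perfect local mixing. ``per_group=True`` additionally
    returns the mean stratified by the focal cell's group."""
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    groups = np.asarray(group_labels)
    n = len(x)
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    neigh = groups[idx[:, 1:]]  # drop self
    uniq = np.unique(groups)
    isi = np.empty(n)
    for i in range(n):
        _, counts = np.unique(neigh[i], return_counts=True)
        p = counts / k
        isi[i] = 1.0 / np.sum(p * p)
    mean_isi = float(isi.mean())
    if per_group:
        strata = {g: float(isi[groups == g].mean()) for g in uniq}
        return mean_isi, strata
    return mean_isi


def resolution_sweep(
    xy_factors=(1, 2, 4),
    n_z=(1, 3),
    localizations=("whole_cell", "membrane"),
    seeds=range(10),
    base_config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Noise-free resolution study: for every (xy factor, z slices,
    localization) setting and seed, simulate, mean-aggregate the clean
    deterministic channel on the downsampled ground-truth mask and score
    AUROC. Returns one row per (setting, seed) plus the per-setting mean."""
    base = base_config or SimulationConfig(field_um=(120.0, 120.0))
    rows = []
    for xy_f, nz, loc, seed in itertools.product(
        xy_factors, n_z, localizations, seeds
    ):
        spec = ChannelSpec(
            "det", mu_neg=0.0, mu_pos=100.0, sigma=0.0, deterministic=True,
            localization=loc, offset=0.0, noise_amplitude=0.0,
        )
        cfg = replace(
            base, channels=[spec], xy_downsample_factor=int(xy_f),
            n_z_slices=int(nz), seed=int(seed),
        )
        ds = simulate_dataset(cfg)
        score = _auroc_on_dataset(ds, "det")
        rows.append(
            {
                "xy_factor": xy_f, "n_z": nz, "localization": loc,
                "seed": seed, "auroc": score,
            }
        )
    return pd.DataFrame(rows)


def _auroc_on_dataset(ds, channel: str, mask: LabelMask | None = None) -> float:
    mask = mask or ds.mask
    means = mean_aggregate(ds.noise_free[channel], mask)
    truth = ds.truth.set_index("cell_id")[f"class_{channel}"]
    common = means.index.intersection(truth.index)
    return auroc(means.loc[common].to_numpy(), truth.loc[common].to_numpy())


METHODS = (
    "mean", "GZ+mean", "blur+mean", "SCI1", "SCI2",
    "GZ+SCI1", "GZ+SCI2", "RATI", "GZ+RATI",
)


def _method_scores(
    image: IntensityImage, mask: LabelMask, method: str, rati_seed: int = 0
) -> pd.Series:
    if method == "mean":
        return mean_aggregate(image, mask)
    if method == "GZ+mean":
        gzf = gz_normalize(image, NeighborhoodSpec())
        return mean_aggregate(gzf.as_image(image), mask)
    if method == "blur+mean":
        return mean_aggregate(box_blur(image, 3), mask)
    if method in ("SCI1", "SCI2", "GZ+SCI1", "GZ+SCI2"):
        params = SCIParams(
            variant=method.removeprefix("GZ+"), use_gz=method.startswith("GZ+")
        )
        _, table = apply_sci(image, mask, params)
        return table["intensity"]
    if method in ("RATI", "GZ+RATI"):
        if method == "GZ+RATI":
            image = gz_normalize(image, NeighborhoodSpec()).as_image(image)
        return rati(image, mask, RATIParams(seed=rati_seed))["intensity"]
    raise ValueError(f"unknown method {method!r}; available: {METHODS}")


def method_comparison(
    image: IntensityImage,
    mask: LabelMask,
    truth: pd.Series,
    methods=METHODS,
    rati_seed: int = 0,
) -> pd.DataFrame:
    """AUROC per aggregation method and its difference to the 'mean'
    baseline on identical inputs. ``truth`` is a binary series indexed by
    cell id."""
    rows = []
    baseline = None
    for method in methods:
        scores = _method_scores(image, mask, method, rati_seed)
        common = scores.index.intersection(truth.index)
        a = auroc(scores.loc[common].to_numpy(), truth.loc[common].to_numpy())
        if method == "mean":
            baseline = a
        rows.append({"method": method, "auroc": a})
    out = pd.DataFrame(rows)
    if baseline is None:
        baseline = out.loc[out["method"] == "mean", "auroc"].iloc[0] if (
            "mean" in set(out["method"])
        ) else np.nan
    out["delta_auroc"] = out["auroc"] - baseline
    return out
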