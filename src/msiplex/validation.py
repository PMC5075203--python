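"""Validation: KL divergence between feature distributions and CMP analysis.

Real-vs-synthetic agreement is scored with the Kullback-Leibler divergence
between histogram estimates on a shared binning; combinatorial molecular
phenotype (CMP) analysis thresholds every imaged channel and summarises the
per-pixel binary presence/absence codes, the analysis surface used for
multiplex immunofluorescence data.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import filters

from .io import ChannelStack
from .learning import LabelMap

EPSILON = 1e-6
DEFAULT_BINS = 30

FEATURES = ["count_per_cell", "D", "minor_axis_ratio", "axes_ratio",
            "solidity", "area_fraction"]


def kl_divergence(real: Sequence[float], synth: Sequence[float],
                  n_bins: int = DEFAULT_BINS) -> float:
    """KL(real || synth) in nats over shared-binning histogram estimates.

    Bins span the pooled range of both samples; empty bins receive additive
    smoothing EPSILON before renormalisation.  Asymmetric by construction.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    real = np.asarray(real, dtype=float)
    synth = np.asarray(synth, dtype=float)
    if real.size == 0 or synth.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(real.min(), synth.min())
    hi = max(real.max(), synth.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(real, bins=edges)
    q, _ = np.histogram(synth, bins=edges)
    p = p.astype(float) + EPSILON
    q = q.astype(float) + EPSILON
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def feature_report(real: pd.DataFrame, synth: pd.DataFrame,
                   n_bins: int = DEFAULT_BINS) -> pd.DataFrame:
    """Per-feature, per-organelle KL divergence matrix (organelle rows)."""
    for df, name in ((real, "real"), (synth, "synth")):
        missing = [f for f in FEATURES if f not in df.columns]
        if missing:
            raise ValueError(f"{name} table missing feature columns {missing}")
    organelles = sorted(set(real["organelle"]) & set(synth["organelle"]))
    if not organelles:
        raise ValueError("no organelle types shared between the two tables")
    rows = {}
    for org in organelles:
        r = real[real["organelle"] == org]
        s = synth[synth["organelle"] == org]
        rows[org] = {
            feat: kl_divergence(r[feat].to_numpy(), s[feat].to_numpy(), n_bins)
            for feat in FEATURES
        }
    return pd.DataFrame.from_dict(rows, orient="index")[FEATURES]


def otsu_thresholds(stack: ChannelStack,
                    channels: Sequence[str] | None = None) -> dict[str, float]:
    names = list(channels) if channels else stack.channel_names
    return {n: float(filters.threshold_otsu(stack.channels[n]))
            for n in names}


def cmp_codes(stack: ChannelStack, thresholds: Mapping[str, float],
              cells: LabelMap | None = None
              ) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-pixel combinatorial molecular phenotype codes.

    Bit c of the code is 1 where channel c is at or above its threshold
    (channel order = iteration order of ``thresholds``).  Returns the code
    image and a summary table with pixel counts per code; when a cell label
    map is supplied, per-cell occupancy columns (fraction of each cell's
    pixels carrying the code) are added.
    """
    names = list(thresholds)
    missing = [n for n in names if n not in stack.channels]
    if missing:
        raise ValueError(f"thresholds name unknown channels {missing}")
    shape = stack.shape
    if cells is not None and cells.labels.shape != shape:
        raise ValueError("cell label map shape mismatch")
    codes = np.zeros(shape, dtype=np.int64)
    for bit, name in enumerate(names):
        codes |= (stack.channels[name] >= thresholds[name]).astype(np.int64) << bit
    values, counts = np.unique(codes, return_counts=True)
    rows = []
    for v, n in zip(values, counts):
        code_str = format(int(v), f"0{len(names)}b")[::-1]  # bit 0 first
        rows.append({"code": code_str, "pixel_count": int(n)})
    table = pd.DataFrame(rows)
    if cells is not None:
        occ: dict[str, dict[int, float]] = {}
        labels = cells.labels
        for cid in np.unique(labels[labels > 0]):
            mask = labels == cid
            total = int(mask.sum())
            vals, cnts = np.unique(codes[mask], return_counts=True)
            for v, n in zip(vals, cnts):
                code_str = format(int(v), f"0{len(names)}b")[::-1]
                occ.setdefault(code_str, {})[int(cid)] = n / total
        table["per_cell_occupancy"] = table["code"].map(
            lambda c: occ.get(c, {}))
    table.attrs["channel_order"] = names
    return codes, table
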