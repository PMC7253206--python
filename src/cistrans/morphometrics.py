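"""Fruit shape descriptors, trait transforms, PCA, and trait-level dominance.

Descriptors follow the ImageJ conventions: aspect ratio AR = MaA/MiA,
roundness Ro = 4A/(pi*MaA^2), circularity Ci = 4*pi*A/perimeter^2. All three
are dimensionless and equal 1 for a perfect circle. Size traits and AR are
log10-transformed; the bounded shape ratios Ro and Ci are arcsine-square-root
transformed before PCA on the correlation matrix.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .dominance import DominanceRecord, degree_of_dominance

logger = logging.getLogger("cistrans")

LOG_TRAITS = ("area", "major_axis", "minor_axis", "aspect_ratio")
ARCSINE_TRAITS = ("roundness", "circularity")
PCA_TRAITS = ("area", "major_axis", "minor_axis", "aspect_ratio", "circularity")


def shape_descriptors(
    area, major_axis, minor_axis, perimeter, literal_circularity: bool = False
):
    """(AR, Ro, Ci) from fruit area, ellipse axes and perimeter.

    ``literal_circularity`` switches Ci to 4*pi*AR/perimeter^2 — a printed
    variant kept behind a flag for audit; the default is the standard ImageJ
    circularity 4*pi*area/perimeter^2.
    """
    area = np.asarray(area, dtype=float)
    major = np.asarray(major_axis, dtype=float)
    minor = np.asarray(minor_axis, dtype=float)
    perim = np.asarray(perimeter, dtype=float)
    if (np.minimum.reduce([area, major, minor, perim]) <= 0).any():
        raise ValueError("all measurements must be positive")
    ar = major / minor
    ro = 4.0 * area / (np.pi * major**2)
    ci = (
        4.0 * np.pi * ar / perim**2
        if literal_circularity
        else 4.0 * np.pi * area / perim**2
    )
    return ar, ro, ci


def add_descriptors(table: pd.DataFrame, literal_circularity: bool = False) -> pd.DataFrame:
    """Append aspect_ratio, roundness and circularity columns."""
    ar, ro, ci = shape_descriptors(
        table["area"], table["major_axis"], table["minor_axis"], table["perimeter"],
        literal_circularity=literal_circularity,
    )
    out = table.copy()
    out["aspect_ratio"], out["roundness"], out["circularity"] = ar, ro, ci
    return out


def transform_traits(table: pd.DataFrame) -> pd.DataFrame:
    """log10 the size traits and AR; arcsine-sqrt the bounded shape ratios.

    Roundness/circularity values slightly above 1 (measurement noise) are
    clipped to [0, 1] with a warning before the arcsine transform.
    """
    out = table.copy()
    for trait in LOG_TRAITS:
        if trait in out:
            vals = out[trait].to_numpy(dtype=float)
            if (vals <= 0).any():
                raise ValueError(f"nonpositive values in log-transformed trait {trait!r}")
            out[trait] = np.log10(vals)
    for trait in ARCSINE_TRAITS:
        if trait in out:
            vals = out[trait].to_numpy(dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                warnings.warn(
                    f"{trait}: values outside [0, 1] clipped before arcsine transform"
                )
                vals = np.clip(vals, 0.0, 1.0)
            out[trait] = np.arcsin(np.sqrt(vals))
    return out


def pca_traits(
    table: pd.DataFrame, scale: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a traits table with a deterministic sign convention.

    Columns are centered and (by default) scaled to unit variance, i.e. PCA
    on the correlation matrix, since the transformed traits mix units.
    Constant columns are dropped with a warning. Each component is oriented
    so its largest-magnitude loading is positive; ``variance_explained``
    sums to 1. Returns (scores, loadings, variance_explained).
    """
    X = table.to_numpy(dtype=float)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("PCA needs at least 2 traits and 3 observations")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(table.columns, keep) if not k]
        warnings.warn(f"constant traits dropped from PCA: {dropped}")
        X, sd = X[:, keep], sd[keep]
    cols = [c for c, k in zip(table.columns, keep) if k]
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / sd
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # orient each PC so its largest-|loading| entry is positive
    flips = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flips[flips == 0] = 1.0
    vt = vt * flips[:, None]
    u = u * flips[None, : u.shape[1]]
    scores = u * s
    var = s**2 / (s**2).sum()
    pcs = [f"PC{i + 1}" for i in range(s.size)]
    return (
        pd.DataFrame(scores, index=table.index, columns=pcs),
        pd.DataFrame(vt.T, index=cols, columns=pcs),
        var,
    )


def trait_dominance(
    values: pd.Series | pd.DataFrame, genotypes: pd.Series, hybrid_label: str = "CxW"
) -> list[DominanceRecord]:
    """Dominance records from per-genotype medians of traits or PC scores."""
    frame = values.to_frame() if isinstance(values, pd.Series) else values
    records = []
    for col in frame.columns:
        med = frame[col].groupby(genotypes).median()
        for geno in ("W", "C", hybrid_label):
            if geno not in med.index:
                raise ValueError(f"genotype {geno!r} missing for trait {col!r}")
        records.append(
            degree_of_dominance(
                med["W"], med["C"], med[hybrid_label], id=str(col)
            )
        )
    return records
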