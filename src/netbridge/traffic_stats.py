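"""Trafficking-screen statistics: traffic efficiency, deviation scores,
per-siRNA effect sums, the full-matrix permutation test, and the
halide-quenching decay fit.

Traffic efficiency (TE) of a cell is the ratio of surface channel signal
(extracellular tag) to total channel signal; an image is summarized by the
median TE over its cells and discarded when it holds fewer than ``min_cells``
cells (default 20).  A condition's deviation score is

    DS = (TE_test - TE_control) / (2 * SEM_control)

so DS = 1 means the test TE sits two control standard errors above the
control mean; positive scores are traffic enhancers, negative are
inhibitors.  Because DS values are normalized by the same plate controls
they are exchangeable across the whole screen matrix, which licenses the
full-matrix permutation null: all individual DS values (every siRNA x
channel-variant x replicate cell) are shuffled together, and each siRNA's
global effect Sigma|<DS_i>| (sum over the three channel variants of the
absolute mean DS) is recomputed per shuffle.  The empirical p is the
fraction of shuffled effects >= the observed one, floored at 1/n_perm.

The functional assay's fluorescence decay traces are normalized to the
pre-addition baseline and fit with offset + amplitude * exp(-rate * t); the
initial influx rate is the slope at t = 0, i.e. -amplitude * rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CFTR_TYPES = ("wt", "F508del", "F508del+VX-809")


@dataclass(frozen=True)
class ImageSummary:
    image_id: str
    median_te: float
    n_cells: int
    qc_pass: bool


@dataclass(frozen=True)
class PermutationResult:
    sirna: str
    observed_sum: float
    per_type_means: dict[str, float]
    p: float
    n_perm: int
    seed: int | None = None


@dataclass(frozen=True)
class DecayFit:
    amplitude: float
    rate: float
    offset: float
    initial_slope: float
    residual_norm: float


def traffic_efficiency(
    surface: np.ndarray | list[float],
    total: np.ndarray | list[float],
    image_id: str = "",
    min_cells: int = 20,
) -> ImageSummary:
    """Median per-cell surface/total ratio for one image, with cell-count QC."""
    surface = np.asarray(surface, dtype=float)
    total = np.asarray(total, dtype=float)
    if surface.shape != total.shape:
        raise ValueError("surface and total signal arrays must align")
    bad = np.nonzero(total <= 0)[0]
    if bad.size:
        raise ValueError(
            f"image {image_id or '<unnamed>'}: non-positive total signal at cell "
            f"index {int(bad[0])}"
        )
    ratios = surface / total
    n = ratios.size
    return ImageSummary(
        image_id=image_id,
        median_te=float(np.median(ratios)) if n else float("nan"),
        n_cells=n,
        qc_pass=n >= min_cells,
    )


def summarize_condition(images: list[ImageSummary]) -> tuple[float, int]:
    """Mean of per-image median TEs over QC-passing images."""
    passed = [im.median_te for im in images if im.qc_pass]
    if not passed:
        raise ValueError("no image passed QC for this condition")
    return float(np.mean(passed)), len(passed)


def control_stats(well_mean_tes: np.ndarray | list[float]) -> tuple[float, float]:
    """Mean and SEM of the negative-control wells on a plate.

    SEM = sample SD of per-well mean TEs / sqrt(n_wells).
    """
    te = np.asarray(well_mean_tes, dtype=float)
    if te.size < 2:
        raise ValueError("need >= 2 control wells to estimate the SEM")
    return float(te.mean()), float(te.std(ddof=1) / np.sqrt(te.size))


def deviation_score(te_test: float, control_mean: float, control_sem: float) -> float:
    """DS = (TE_test - TE_control) / (2 * SEM_control)."""
    if control_sem <= 0:
        raise ValueError("control SEM must be positive")
    return (te_test - control_mean) / (2.0 * control_sem)


def _check_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    required = {"sirna", "cftr_type", "replicate", "ds"}
    missing = required - set(matrix.columns)
    if missing:
        raise ValueError(f"DS matrix missing columns: {sorted(missing)}")
    if not np.isfinite(matrix["ds"]).all():
        raise ValueError("DS matrix contains non-finite values")
    return matrix


def sirna_effect(matrix: pd.DataFrame, sirna: str) -> tuple[float, dict[str, float]]:
    """Global effect Sigma|<DS_i>| of one siRNA and the per-type mean DS.

    ``matrix`` is long format with columns sirna, cftr_type, replicate, ds.
    Every channel variant present in the matrix must have replicates for
    this siRNA.
    """
    _check_matrix(matrix)
    sub = matrix[matrix["sirna"] == sirna]
    if sub.empty:
        raise ValueError(f"siRNA {sirna!r} absent from matrix")
    types = sorted(matrix["cftr_type"].unique())
    means: dict[str, float] = {}
    for t in types:
        vals = sub.loc[sub["cftr_type"] == t, "ds"]
        if vals.empty:
            raise ValueError(f"siRNA {sirna!r} has no DS values for type {t!r}")
        means[t] = float(vals.mean())
    return float(sum(abs(m) for m in means.values())), means


def _pivot(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """DS values as an array (sirna, type, replicate); requires a complete design."""
    sirnas = sorted(matrix["sirna"].unique())
    types = sorted(matrix["cftr_type"].unique())
    counts = matrix.groupby(["sirna", "cftr_type"]).size()
    n_rep = int(counts.iloc[0])
    if not (counts == n_rep).all() or len(counts) != len(sirnas) * len(types):
        raise ValueError("permutation test requires a complete balanced DS matrix")
    ordered = matrix.sort_values(["sirna", "cftr_type", "replicate"])
    values = ordered["ds"].to_numpy().reshape(len(sirnas), len(types), n_rep)
    return values, sirnas


def permutation_test(
    matrix: pd.DataFrame,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> list[PermutationResult]:
    """Full-matrix permutation test of each siRNA's Sigma|<DS_i>|.

    All individual DS cells are shuffled jointly across siRNAs, channel
    variants and replicates; per shuffle the per-siRNA effect sums are
    recomputed.  p = max(count >= observed, 1) / n_perm.
    """
    import warnings

    _check_matrix(matrix)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives very coarse p-value resolution")
    seed = rng if isinstance(rng, int) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    values, sirnas = _pivot(matrix)
    n_s, n_t, n_r = values.shape
    flat = values.reshape(-1)
    observed = np.abs(values.mean(axis=2)).sum(axis=1)

    # permute in chunks: each row of perm is one shuffled matrix
    counts = np.zeros(n_s, dtype=np.int64)
    chunk = max(1, min(n_perm, 2_000_000 // max(flat.size, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = gen.permuted(np.tile(flat, (m, 1)), axis=1)
        shuffled = perms.reshape(m, n_s, n_t, n_r)
        sums = np.abs(shuffled.mean(axis=3)).sum(axis=2)  # (m, n_s)
        counts += (sums >= observed[None, :]).sum(axis=0)
        done += m

    results = []
    for i, s in enumerate(sirnas):
        _, means = sirna_effect(matrix, s)
        results.append(
            PermutationResult(
                sirna=s,
                observed_sum=float(observed[i]),
                per_type_means=means,
                p=max(int(counts[i]), 1) / n_perm,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results


def fit_decay(
    t: np.ndarray | list[float],
    f: np.ndarray | list[float],
    baseline_end: float,
    with_offset: bool = True,
) -> DecayFit:
    """Fit normalized fluorescence F/F0 with an exponential decay.

    Samples at ``t < baseline_end`` form the pre-addition baseline; F is
    divided by their mean (so the baseline sits at 1) and the decay model
    ``offset + amplitude * exp(-rate * (t - baseline_end))`` is least-squares
    fit to the post-addition samples.  The initial influx rate is the slope
    at the moment of addition, ``-amplitude * rate``.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    base = f[t < baseline_end]
    post = t >= baseline_end
    if base.size < 1 or post.sum() < 10:
        raise ValueError("need baseline samples and >= 10 post-addition samples")
    f0 = base.mean()
    if f0 <= 0:
        raise ValueError("baseline mean must be positive")
    y = f / f0
    tt = t[post] - baseline_end
    yy = y[post]

    span = yy[0] - yy[-1]
    if with_offset:
        model = lambda x, amp, rate, off: off + amp * np.exp(-rate * x)
        p0 = [span if abs(span) > 1e-12 else 1e-6, 1.0 / max(tt[-1], 1e-9), yy[-1]]
        bounds = ([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf])
    else:
        model = lambda x, amp, rate: amp * np.exp(-rate * x)
        p0 = [yy[0] if abs(yy[0]) > 1e-12 else 1e-6, 1.0 / max(tt[-1], 1e-9)]
        bounds = ([-np.inf, 0.0], [np.inf, np.inf])
    try:
        popt, _ = curve_fit(model, tt, yy, p0=p0, bounds=bounds, maxfev=20_000)
    except RuntimeError as exc:  # pragma: no cover - solver failure path
        raise ValueError(f"decay fit did not converge: {exc}") from exc
    resid = yy - model(tt, *popt)
    if with_offset:
        amp, rate, off = popt
    else:
        amp, rate = popt
        off = 0.0
    return DecayFit(
        amplitude=float(amp),
        rate=float(rate),
        offset=float(off),
        initial_slope=float(-amp * rate),
        residual_norm=float(np.linalg.norm(resid)),
    )


def surface_retention(signal: float, reference: float) -> float:
    """Surface signal as a percentage of a reference condition's signal."""
    if reference <= 0:
        raise ValueError("reference ratio must be positive")
    return 100.0 * signal / reference
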