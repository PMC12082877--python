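"""Membrane-integrity colocalization: Pearson, Costes threshold, Manders.

The integrity readout per image is the pair of Manders coefficients between
the matrix (IMM, channel A) and outer-membrane (OMM, channel B) signals:
M1 is the fraction of matrix intensity lying on above-threshold OMM pixels,
M2 the converse.  Thresholds come from the Costes automatic procedure:
descend along the orthogonal regression line of B on A until the pixels
below both thresholds are uncorrelated.  The result is controlled by the
Costes block-randomization test, which shuffles square tiles of one channel
to build a null distribution of the Pearson coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ColocError, ConfigError
from .image import TwoChannelImage


@dataclass(frozen=True)
class CostesThreshold:
    """Paired automatic thresholds from the Costes descent.

    ``t_b = slope * t_a + intercept`` with (slope, intercept) the orthogonal
    (total-least-squares) regression of B on A.  ``r_below`` is the Pearson
    coefficient of sub-threshold pixels at the stop point; ``floor`` is set
    when the scan exhausted all intensity levels without the sub-threshold
    correlation turning nonpositive.
    """

    slope: float
    intercept: float
    t_a: float
    t_b: float
    r_below: float
    floor: bool = False


@dataclass(frozen=True)
class ColocResult:
    """Per-image colocalization summary."""

    pearson_r: float
    m1: float
    m2: float
    thresholds: CostesThreshold
    randomization_p: float
    null_mean: float
    null_sd: float
    n_rounds: int
    block_size_px: int


@dataclass(frozen=True)
class Cytofluorogram:
    """Paired per-pixel intensities of the analyzed region."""

    a: np.ndarray
    b: np.ndarray


def _flat_pair(ch_a, ch_b, mask=None):
    a = np.asarray(ch_a, dtype=float).ravel()
    b = np.asarray(ch_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ConfigError("channels must share shape")
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if m.shape != a.shape:
            raise ConfigError("mask must share the channel shape")
        a, b = a[m], b[m]
    return a, b


def pearson(ch_a, ch_b, mask=None) -> float:
    """Sample Pearson correlation over analyzed pixels.

    Raises :class:`ColocError` for fewer than two pixels or a constant
    channel (undefined correlation).
    """
    a, b = _flat_pair(ch_a, ch_b, mask)
    if a.size < 2:
        raise ColocError("need at least 2 analyzed pixels")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ColocError("constant channel: correlation undefined")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def orthogonal_regression(ch_a, ch_b, mask=None) -> tuple[float, float]:
    """Total-least-squares line B ~ slope*A + intercept.

    The slope is taken from the principal axis of the joint intensity
    distribution.  A nonpositive slope means the channels are anticorrelated
    and the Costes descent is meaningless; this raises :class:`ColocError`.
    """
    a, b = _flat_pair(ch_a, ch_b, mask)
    if a.std() == 0 or b.std() == 0:
        raise ColocError("constant channel: degenerate regression")
    cov = np.cov(np.vstack([a, b]))
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    if major[0] == 0:
        raise ColocError("vertical principal axis: slope undefined")
    slope = major[1] / major[0]
    if slope <= 0:
        raise ColocError(
            f"orthogonal regression slope {slope:.4g} is not positive; "
            "channels lack a joint positive trend, Costes descent refused"
        )
    intercept = b.mean() - slope * a.mean()
    return float(slope), float(intercept)


def costes_auto_threshold(ch_a, ch_b, mask=None) -> CostesThreshold:
    """Costes automatic paired thresholds.

    Scans ``T_A`` downward through the observed intensity levels of channel
    A starting at its maximum; at each level the Pearson coefficient of the
    pixels with ``A < T_A`` and ``B < slope*T_A + intercept`` is evaluated
    (levels where it is undefined are skipped), and the scan stops at the
    first level where it is nonpositive.  Exhausting all levels sets the
    floor flag with ``T_A`` at the channel minimum.

    The step size of one observed level makes the scan exact: it visits
    every achievable sub-threshold pixel set.
    """
    a, b = _flat_pair(ch_a, ch_b, mask)
    slope, intercept = orthogonal_regression(a, b)
    # pixel i is below the paired thresholds at level T iff
    # max(a_i, (b_i - intercept)/slope) < T
    t_leave = np.maximum(a, (b - intercept) / slope)
    order = np.argsort(t_leave, kind="stable")
    ts = t_leave[order]
    ao, bo = a[order], b[order]
    c_a = np.concatenate([[0.0], np.cumsum(ao)])
    c_b = np.concatenate([[0.0], np.cumsum(bo)])
    c_aa = np.concatenate([[0.0], np.cumsum(ao * ao)])
    c_bb = np.concatenate([[0.0], np.cumsum(bo * bo)])
    c_ab = np.concatenate([[0.0], np.cumsum(ao * bo)])

    levels = np.unique(a)[::-1]  # descending observed A levels
    for t_a in levels:
        k = int(np.searchsorted(ts, t_a, side="left"))
        if k < 2:
            continue
        n = float(k)
        var_a = c_aa[k] - c_a[k] ** 2 / n
        var_b = c_bb[k] - c_b[k] ** 2 / n
        if var_a <= 0 or var_b <= 0:
            continue
        cov_ab = c_ab[k] - c_a[k] * c_b[k] / n
        r = cov_ab / np.sqrt(var_a * var_b)
        if r <= 0:
            return CostesThreshold(
                slope, intercept, float(t_a), float(slope * t_a + intercept),
                float(r), floor=False,
            )
    t_floor = float(a.min())
    k = int(np.searchsorted(ts, t_floor, side="left"))
    r_below = float("nan")
    return CostesThreshold(
        slope, intercept, t_floor, float(slope * t_floor + intercept),
        r_below, floor=True,
    )


def manders(
    ch_a, ch_b, t_a: float, t_b: float, mask=None, mode: str = "thresholded"
) -> tuple[float, float]:
    """Manders split coefficients at paired thresholds.

    With A the matrix (IMM) and B the membrane (OMM) channel:
    ``M1 = sum(A where A > t_a and B > t_b) / denom_A`` and M2 with the
    roles swapped.  ``mode="thresholded"`` (the JaCoP thresholded variant)
    uses the above-own-threshold intensity sum as the denominator;
    ``mode="classic"`` uses the whole-channel sum.  At zero thresholds on
    nonnegative images both coincide.
    """
    a, b = _flat_pair(ch_a, ch_b, mask)
    above_a = a > t_a
    above_b = b > t_b
    if mode == "thresholded":
        denom_a = a[above_a].sum()
        denom_b = b[above_b].sum()
    elif mode == "classic":
        denom_a = a.sum()
        denom_b = b.sum()
    else:
        raise ConfigError(f"unknown manders mode {mode!r}")
    if denom_a <= 0 or denom_b <= 0:
        raise ColocError("no above-threshold intensity in a reference channel")
    m1 = a[above_a & above_b].sum() / denom_a
    m2 = b[above_a & above_b].sum() / denom_b
    return float(m1), float(m2)


def costes_randomization(
    ch_a,
    ch_b,
    block_size_px: int = 5,
    n_rounds: int = 199,
    seed: int = 0,
) -> tuple[float, float, float, float]:
    """Costes block-shuffling significance test of the observed Pearson r.

    Channel B is partitioned into ``block_size_px`` square tiles (both
    channels cropped to whole tiles); tile positions are permuted
    ``n_rounds`` times and the Pearson coefficient against channel A
    recomputed each round.  Returns ``(p, null_mean, null_sd, r_obs)`` with
    the add-one estimator ``p = (1 + #{null r >= r_obs}) / (n_rounds + 1)``,
    which never reaches zero.
    """
    a = np.asarray(ch_a, dtype=float)
    b = np.asarray(ch_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ConfigError("channels must be 2-D arrays of equal shape")
    if n_rounds < 1:
        raise ConfigError("n_rounds must be >= 1")
    s = block_size_px
    ny, nx = (a.shape[0] // s) * s, (a.shape[1] // s) * s
    n_tiles = (ny // s) * (nx // s)
    if s <= 0 or n_tiles < 2:
        raise ConfigError(
            f"block size {s} px leaves fewer than 2 whole tiles in {a.shape}"
        )
    ac = a[:ny, :nx]
    bc = b[:ny, :nx]
    r_obs = pearson(ac, bc)
    # tiles as a (n_tiles, s, s) stack
    tiles = (
        bc.reshape(ny // s, s, nx // s, s).transpose(0, 2, 1, 3).reshape(-1, s, s)
    )
    rng = np.random.default_rng(seed)
    null = np.empty(n_rounds)
    af = ac.ravel()
    af_c = af - af.mean()
    af_ss = np.sqrt((af_c**2).sum())
    for i in range(n_rounds):
        perm = rng.permutation(n_tiles)
        shuffled = (
            tiles[perm]
            .reshape(ny // s, nx // s, s, s)
            .transpose(0, 2, 1, 3)
            .reshape(ny, nx)
        )
        bf = shuffled.ravel()
        bf_c = bf - bf.mean()
        denom = af_ss * np.sqrt((bf_c**2).sum())
        null[i] = (af_c @ bf_c) / denom if denom > 0 else 0.0
    p = (1 + int(np.sum(null >= r_obs))) / (n_rounds + 1)
    return float(p), float(null.mean()), float(null.std()), float(r_obs)


def cytofluorogram(ch_a, ch_b, mask=None) -> Cytofluorogram:
    """Paired per-pixel intensity samples (no binning)."""
    a, b = _flat_pair(ch_a, ch_b, mask)
    if a.size < 1:
        raise ConfigError("need at least one analyzed pixel")
    return Cytofluorogram(a=a, b=b)


def analyze_coloc(
    image: TwoChannelImage,
    block_size_px: int = 5,
    n_rounds: int = 199,
    seed: int = 0,
    threshold_mode: str = "costes",
    mask=None,
) -> ColocResult:
    """Full per-image integrity readout.

    Channel A is the matrix (IMM) signal and channel B the OMM signal, so
    M1 measures matrix->membrane overlap and M2 membrane->matrix overlap.
    ``threshold_mode`` is ``"costes"`` (default) or ``"zero"`` (classic
    coefficients at zero thresholds).
    """
    a, b = image.channel_imm, image.channel_omm
    if threshold_mode == "costes":
        thr = costes_auto_threshold(a, b, mask)
    elif threshold_mode == "zero":
        slope, intercept = orthogonal_regression(a, b, mask)
        thr = CostesThreshold(slope, intercept, 0.0, 0.0, float("nan"), floor=False)
    else:
        raise ConfigError(f"unknown threshold_mode {threshold_mode!r}")
    m1, m2 = manders(a, b, thr.t_a, thr.t_b, mask)
    p, mu, sd, r_obs = costes_randomization(
        a, b, block_size_px=block_size_px, n_rounds=n_rounds, seed=seed
    )
    return ColocResult(
        pearson_r=r_obs,
        m1=m1,
        m2=m2,
        thresholds=thr,
        randomization_p=p,
        null_mean=mu,
        null_sd=sd,
        n_rounds=n_rounds,
        block_size_px=block_size_px,
    )
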