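"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest


def shapely_hull_mask(mask: np.ndarray) -> np.ndarray:
    """Independent convex-hull rasterization oracle.

    Builds the hull with shapely (a different geometry stack from the
    implementation's Qhull + integer half-plane test) and rasterizes by
    distance-to-hull < 1e-9, which includes pixel centers exactly on an
    edge. Handles point/segment/polygon degeneracies uniformly.
    """
    import shapely
    from shapely.geometry import MultiPoint

    pts = np.argwhere(mask)
    hull = MultiPoint(pts.tolist()).convex_hull
    coords = np.argwhere(np.ones_like(mask, bool)).astype(float)
    inside = shapely.dwithin(hull, shapely.points(coords[:, 0], coords[:, 1]), 1e-9)
    return inside.reshape(mask.shape)


def brute_local_entropy(binned: np.ndarray, window: int) -> np.ndarray:
    """Naive per-pixel histogram entropy, window clipped at borders."""
    h, w = binned.shape
    r = window // 2
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win = binned[max(0, i - r) : i + r + 1, max(0, j - r) : j + r + 1].ravel()
            p = np.bincount(win) / win.size
            p = p[p > 0]
            out[i, j] = -(p * np.log2(p)).sum()
    return out


def hand_km(times, events):
    """Hand product-limit estimator: list of (event_time, S)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    curve = []
    for t in sorted(set(times[events == 1])):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / n_at_risk
        curve.append((t, s))
    return curve


def hand_logrank(times_a, events_a, times_b, events_b):
    """Hypergeometric-term log-rank chi-square, computed from scratch."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    o_minus_e = 0.0
    v = 0.0
    for t in sorted(set(all_t[all_e == 1])):
        n1 = (ta >= t).sum()
        n2 = (tb >= t).sum()
        n = n1 + n2
        d = ((all_t == t) & (all_e == 1)).sum()
        d1 = ((ta == t) & (ea == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0
    return o_minus_e**2 / v


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def disk_mask():
    """Digital disk of radius 20 on a 51x51 grid."""
    rr, cc = np.mgrid[0:51, 0:51]
    return (rr - 25) ** 2 + (cc - 25) ** 2 <= 400


def all_binary_masks(shape):
    """Every nonempty binary mask of the given (small) shape."""
    n = shape[0] * shape[1]
    for code in range(1, 1 << n):
        yield np.array([(code >> i) & 1 for i in range(n)], bool).reshape(shape)
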