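"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by the most transparent route available
(naive loops, exhaustive graph construction, direct definitions) so the
optimized library code can be checked against it.
"""

from __future__ import annotations

import numpy as np


def naive_link_events(frames, xs, ys, radius, gap):
    """Greedy frame-ordered linker, written as a direct O(n^2) transcription.

    Returns a list of sets of row indices (the event partition).  Rules:
    walk rows in frame order; a row joins the open event (last frame >=
    f - gap - 1) whose running centroid is nearest within ``radius``;
    ties to the earlier-created event; otherwise it opens a new event.
    """
    events = []  # each: dict(rows=[...], last=int, created=int)
    order = np.argsort(np.asarray(frames), kind="stable")
    for i in order:
        f = frames[i]
        best = None
        best_key = None
        for e in events:
            if e["last"] < f - gap - 1:
                continue
            cx = np.mean([xs[j] for j in e["rows"]])
            cy = np.mean([ys[j] for j in e["rows"]])
            d2 = (cx - xs[i]) ** 2 + (cy - ys[i]) ** 2
            if d2 <= radius ** 2:
                key = (d2, e["created"])
                if best_key is None or key < best_key:
                    best, best_key = e, key
        if best is None:
            events.append({"rows": [int(i)], "last": int(f),
                           "created": len(events)})
        else:
            best["rows"].append(int(i))
            best["last"] = max(best["last"], int(f))
    return [frozenset(e["rows"]) for e in events]


def connected_components_eps(xy, eps):
    """Exhaustive connected components of the <= eps adjacency graph."""
    n = len(xy)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1]) <= eps:
                parent[find(i)] = find(j)
    labels = np.array([find(i) for i in range(n)])
    comps = {}
    for i, lab in enumerate(labels):
        comps.setdefault(lab, set()).add(i)
    return [frozenset(c) for c in comps.values()]


def double_loop_sofi2(stack, lag):
    """Second-order lagged cumulant by explicit per-pixel loops."""
    stack = np.asarray(stack, dtype=float)
    n, h, w = stack.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            ts = stack[:, i, j]
            d = ts - ts.mean()
            if lag == 0:
                out[i, j] = np.mean(d * d)
            else:
                acc = 0.0
                for t in range(n - lag):
                    acc += d[t] * d[t + lag]
                out[i, j] = acc / (n - lag)
    return out


def direct_frc_resolution(a, b, pixel, threshold=1.0 / 7.0):
    """FRC resolution by direct definitions: plain FFT, per-pixel ring
    accumulation with explicit loops over frequency bins, linear
    interpolation of the first downward threshold crossing.

    No padding, no apodization — an independent route to the same
    physical quantity on same-size square inputs.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    assert a.shape == b.shape and a.shape[0] == a.shape[1]
    n = a.shape[0]
    fa = np.fft.fftshift(np.fft.fft2(a))
    fb = np.fft.fftshift(np.fft.fft2(b))
    c = n // 2
    nring = n // 2
    num = np.zeros(nring)
    p1 = np.zeros(nring)
    p2 = np.zeros(nring)
    for i in range(n):
        for j in range(n):
            r = int(round(np.hypot(i - c, j - c)))
            if 0 < r < nring:
                num[r] += (fa[i, j] * np.conj(fb[i, j])).real
                p1[r] += abs(fa[i, j]) ** 2
                p2[r] += abs(fb[i, j]) ** 2
    corr = np.zeros(nring)
    for r in range(1, nring):
        den = np.sqrt(p1[r] * p2[r])
        corr[r] = num[r] / den if den > 0 else 0.0
    freqs = np.arange(nring) / (n * pixel)
    for r in range(2, nring):
        if corr[r] < threshold <= corr[r - 1]:
            f0, f1 = freqs[r - 1], freqs[r]
            c0, c1 = corr[r - 1], corr[r]
            fc = f0 + (c0 - threshold) / (c0 - c1) * (f1 - f0)
            return 1.0 / fc
    return 2.0 * pixel


def point_to_polyline_distance(p, polyline):
    """Minimum distance from a 2D point to a polyline (segment-wise)."""
    best = np.inf
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
        best = min(best, float(np.linalg.norm(a + t * ab - p)))
    return best
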