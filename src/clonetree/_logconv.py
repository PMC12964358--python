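"""Log-space trapezoid convolution kernels.

The simplex integral of a product of per-node mass densities is a
chain of continuous convolutions evaluated at total mass one.  Each
convolution is discretized with the composite trapezoid rule on the
shared grid: ``out[k] = log sum_{i+j=k} t(i) exp(a[i] + b[j])`` with
endpoint weights ``t(0) = t(k) = 1/2``, so the iterated rule is
second-order accurate.  The grid-step factor ``h`` per convolution is
omitted; it cancels against the prior-mass normalization, which is
computed with the same kernel.  Entries span thousands of nats, so
the sum uses a per-output-cell max shift rather than one global
rescale.  A numba kernel is used when available; the numpy fallback
is exact but slower.
"""

from __future__ import annotations

import numpy as np

__all__ = ["log_conv", "log_conv_many"]

_LOG_HALF = float(np.log(0.5))


def _log_conv_numpy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    G = a.shape[0]
    out = np.full(G, -np.inf)
    for k in range(1, G):
        seg = a[: k + 1] + b[k::-1]
        seg[0] += _LOG_HALF
        seg[-1] += _LOG_HALF
        m = seg.max()
        if m == -np.inf:
            continue
        out[k] = m + np.log(np.exp(seg - m).sum())
    return out


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True)
    def _log_conv_numba(a, b):  # type: ignore[no-redef]
        G = a.shape[0]
        out = np.empty(G)
        out[0] = -np.inf
        log_half = -0.6931471805599453
        for k in range(1, G):
            m = -np.inf
            for i in range(k + 1):
                v = a[i] + b[k - i]
                if i == 0 or i == k:
                    v += log_half
                if v > m:
                    m = v
            if m == -np.inf:
                out[k] = -np.inf
                continue
            s = 0.0
            for i in range(k + 1):
                v = a[i] + b[k - i]
                if i == 0 or i == k:
                    v += log_half
                if v != -np.inf:
                    s += np.exp(v - m)
            out[k] = m + np.log(s)
        return out

    def log_conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Trapezoid log convolution truncated to the grid length."""
        return _log_conv_numba(
            np.ascontiguousarray(a, dtype=np.float64),
            np.ascontiguousarray(b, dtype=np.float64),
        )

except Exception:  # pragma: no cover

    def log_conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Trapezoid log convolution truncated to the grid length."""
        return _log_conv_numpy(np.asarray(a, float), np.asarray(b, float))


def log_conv_many(arrays) -> np.ndarray:
    """Fold :func:`log_conv` over a sequence of log-mass vectors."""
    it = iter(arrays)
    acc = np.asarray(next(it), float)
    for arr in it:
        acc = log_conv(acc, arr)
    return acc
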