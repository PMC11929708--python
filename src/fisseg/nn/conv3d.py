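"""Forward-only 3D convolution primitives (numpy, channels-first).

Used by the pre-segmentation CNN, which runs inference only; gradients are
never taken through these ops.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> np.ndarray:
    """x: (C_in, D, H, W); w: (C_out, C_in/groups, k, k, k) -> (C_out, ...)."""
    c_in = x.shape[0]
    c_out, cpg, k = w.shape[0], w.shape[1], w.shape[2]
    if padding:
        x = np.pad(x, ((0, 0),) + ((padding, padding),) * 3)
    if k == 1 and groups == 1:
        out = np.tensordot(w[:, :, 0, 0, 0], x[:, ::stride, ::stride, ::stride],
                           axes=(1, 0))
    else:
        win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
        win = win[:, ::stride, ::stride, ::stride]
        sp = win.shape[1:4]
        if groups == c_in and cpg == 1 and c_out == c_in:  # depthwise
            out = np.einsum("cdhwijk,cijk->cdhw", win, w[:, 0],
                            optimize=True)
        elif groups == 1:
            flat = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(
                -1, c_in * k ** 3)
            out = (flat @ w.reshape(c_out, -1).T).T.reshape((c_out,) + sp)
        else:
            outs = []
            for g in range(groups):
                xg = win[g * cpg:(g + 1) * cpg]
                wg = w[g * (c_out // groups):(g + 1) * (c_out // groups)]
                flat = xg.transpose(1, 2, 3, 0, 4, 5, 6).reshape(
                    -1, cpg * k ** 3)
                outs.append((flat @ wg.reshape(len(wg), -1).T).T.reshape(
                    (len(wg),) + sp))
            out = np.concatenate(outs, axis=0)
    out = np.ascontiguousarray(out, dtype=np.float32)
    if b is not None:
        out += b[:, None, None, None]
    return out


def upsample_trilinear(x: np.ndarray, target_shape) -> np.ndarray:
    """Trilinear upsampling of (C, D, H, W) to (C,) + target_shape."""
    from scipy.ndimage import zoom

    factors = [t / s for t, s in zip(target_shape, x.shape[1:])]
    out = np.stack([
        zoom(x[c], factors, order=1, grid_mode=True, mode="nearest")
        for c in range(x.shape[0])
    ])
    # zoom may be off by one voxel from rounding; crop/pad defensively
    out = out[:, :target_shape[0], :target_shape[1], :target_shape[2]]
    pads = [(0, t - s) for t, s in zip(target_shape, out.shape[1:])]
    if any(p[1] for p in pads):
        out = np.pad(out, [(0, 0)] + pads, mode="edge")
    return out.astype(np.float32)


def hardswish(x):
    return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0


def hardsigmoid(x):
    return np.clip(x + 3.0, 0.0, 6.0) / 6.0
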