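"""Numba kernels for 3-D convolution via im2col / col2im.

Patch matrices are written row-contiguously (streaming stores) while the
padded activation grid is read through the cache; the matrix product itself
is delegated to BLAS by the caller. Layout is channels-last throughout:
activations ``(N, D, H, W, C)``, patch matrix ``(N*Do*Ho*Wo, 27*C)``.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["im2col_3x3x3", "col2im_3x3x3"]


@njit(cache=True, fastmath=True)
def im2col_3x3x3(xp, cols, stride, Do, Ho, Wo):
    """Gather 3x3x3 patches of padded grid ``xp`` into ``cols``.

    xp : (N, Dp, Hp, Wp, C) float32, already SAME-padded
    cols : (N*Do*Ho*Wo, 27*C) float32, overwritten
    """
    N = xp.shape[0]
    C = xp.shape[4]
    r = 0
    for n in range(N):
        for d in range(Do):
            d0 = d * stride
            for h in range(Ho):
                h0 = h * stride
                for w in range(Wo):
                    w0 = w * stride
                    q = 0
                    for i in range(3):
                        for j in range(3):
                            for k in range(3):
                                for c in range(C):
                                    cols[r, q] = xp[n, d0 + i, h0 + j, w0 + k, c]
                                    q += 1
                    r += 1


@njit(cache=True, fastmath=True)
def col2im_3x3x3(dcols, dxp, stride, Do, Ho, Wo):
    """Scatter-add patch gradients back onto the padded grid gradient."""
    N = dxp.shape[0]
    C = dxp.shape[4]
    r = 0
    for n in range(N):
        for d in range(Do):
            d0 = d * stride
            for h in range(Ho):
                h0 = h * stride
                for w in range(Wo):
                    w0 = w * stride
                    q = 0
                    for i in range(3):
                        for j in range(3):
                            for k in range(3):
                                for c in range(C):
                                    dxp[n, d0 + i, h0 + j, w0 + k, c] += dcols[r, q]
                                    q += 1
                    r += 1
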