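"""Numba kernels for the single-layer GRU regressor.

Cell convention (reset gate applied before the candidate's recurrent
matmul; update gate ``z`` carries the previous state):

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
    c_t = phi(x_t Wc + (r_t * h_{t-1}) Uc + bc)
    h_t = z_t * h_{t-1} + (1 - z_t) * c_t

followed by (inverted) dropout on the final state during training and a
single dense output unit.  Training is plain mini-batch Adam on the mean
absolute error, with full backpropagation through time; batches are taken
in time order unless shuffling is requested.  Everything is float32.

Weight layout: ``W (p, 3h)`` packs the input kernels ``[Wz | Wr | Wc]``,
``U (h, 2h)`` packs ``[Uz | Ur]``, ``Uc (h, h)`` is the candidate's
recurrent kernel, ``b (3h)`` the gate biases, ``Wo (h,)``/``bo`` the
output layer.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Activation codes (order matches the tuning grid documentation).
ACTIVATIONS = ["tanh", "relu", "sigmoid", "softplus", "softsign", "selu", "elu", "exponential"]

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


@njit(cache=True, inline="always")
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _act_value_grad(a, code, v, g):
    """Elementwise activation value and derivative at preactivation ``a``."""
    B, H = a.shape
    for i in range(B):
        for j in range(H):
            x = a[i, j]
            if code == 0:  # tanh
                t = np.tanh(x)
                v[i, j] = t
                g[i, j] = 1.0 - t * t
            elif code == 1:  # relu
                if x > 0.0:
                    v[i, j] = x
                    g[i, j] = 1.0
                else:
                    v[i, j] = 0.0
                    g[i, j] = 0.0
            elif code == 2:  # sigmoid
                s = _sigmoid(x)
                v[i, j] = s
                g[i, j] = s * (1.0 - s)
            elif code == 3:  # softplus
                if x > 20.0:
                    v[i, j] = x
                else:
                    v[i, j] = np.log1p(np.exp(x))
                g[i, j] = _sigmoid(x)
            elif code == 4:  # softsign
                d = 1.0 + abs(x)
                v[i, j] = x / d
                g[i, j] = 1.0 / (d * d)
            elif code == 5:  # selu
                if x > 0.0:
                    v[i, j] = _SELU_LAMBDA * x
                    g[i, j] = _SELU_LAMBDA
                else:
                    e = np.exp(x)
                    v[i, j] = _SELU_LAMBDA * _SELU_ALPHA * (e - 1.0)
                    g[i, j] = _SELU_LAMBDA * _SELU_ALPHA * e
            elif code == 6:  # elu
                if x > 0.0:
                    v[i, j] = x
                    g[i, j] = 1.0
                else:
                    e = np.exp(x)
                    v[i, j] = e - 1.0
                    g[i, j] = e
            else:  # exponential
                e = np.exp(x)
                v[i, j] = e
                g[i, j] = e


@njit(cache=True)
def gru_forward(X, W, U, Uc, b, Wo, bo, act_code):
    """Deterministic forward pass (no dropout). X: (n, k, p) float32."""
    n, k, p = X.shape
    h = Uc.shape[0]
    yhat = np.empty(n, dtype=np.float32)
    if n == 0:
        return yhat
    H = np.zeros((n, h), dtype=np.float32)
    xt = np.empty((n, p), dtype=np.float32)
    cval = np.empty((n, h), dtype=np.float32)
    cgrad = np.empty((n, h), dtype=np.float32)
    for t in range(k):
        for i in range(n):
            for j in range(p):
                xt[i, j] = X[i, t, j]
        ax = np.dot(xt, W)  # (n, 3h)
        hU = np.dot(H, U)  # (n, 2h)
        rh = np.empty((n, h), dtype=np.float32)
        z = np.empty((n, h), dtype=np.float32)
        for i in range(n):
            for j in range(h):
                z[i, j] = _sigmoid(ax[i, j] + hU[i, j] + b[j])
                r = _sigmoid(ax[i, h + j] + hU[i, h + j] + b[h + j])
                rh[i, j] = r * H[i, j]
        ac = np.dot(rh, Uc)
        for i in range(n):
            for j in range(h):
                ac[i, j] = ac[i, j] + ax[i, 2 * h + j] + b[2 * h + j]
        _act_value_grad(ac, act_code, cval, cgrad)
        for i in range(n):
            for j in range(h):
                H[i, j] = z[i, j] * H[i, j] + (1.0 - z[i, j]) * cval[i, j]
    for i in range(n):
        acc = bo[0]
        for j in range(h):
            acc += H[i, j] * Wo[j]
        yhat[i] = acc
    return yhat


@njit(cache=True)
def _adam_update(p, g, m, v, t, lr, b1, b2, eps):
    n = p.size
    pf = p.reshape(n)
    gf = g.reshape(n)
    mf = m.reshape(n)
    vf = v.reshape(n)
    c1 = 1.0 - b1 ** t
    c2 = 1.0 - b2 ** t
    for i in range(n):
        mf[i] = b1 * mf[i] + (1.0 - b1) * gf[i]
        vf[i] = b2 * vf[i] + (1.0 - b2) * gf[i] * gf[i]
        pf[i] -= lr * (mf[i] / c1) / (np.sqrt(vf[i] / c2) + eps)


@njit(cache=True)
def gru_train(
    X,
    y,
    Xval,
    yval,
    W,
    U,
    Uc,
    b,
    Wo,
    bo,
    act_code,
    epochs,
    batch_size,
    lr,
    dropout,
    seed,
    shuffle,
    history,
):
    """Train in place; fill ``history`` (2, epochs) with train/val MAE.

    Returns 0 on success, 1 if the loss became non-finite (diverged).
    Validation rows are used for curve logging only, never for updates.
    """
    n, k, p = X.shape
    h = Uc.shape[0]
    np.random.seed(seed)
    b1, b2, eps = 0.9, 0.999, 1e-7
    keep = 1.0 - dropout
    n_batches = (n + batch_size - 1) // batch_size

    # Adam state
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    mU = np.zeros_like(U); vU = np.zeros_like(U)
    mUc = np.zeros_like(Uc); vUc = np.zeros_like(Uc)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    mWo = np.zeros_like(Wo); vWo = np.zeros_like(Wo)
    mbo = np.zeros_like(bo); vbo = np.zeros_like(bo)

    order = np.arange(n)
    adam_t = 0
    for epoch in range(epochs):
        if shuffle:
            # Fisher-Yates with numba's seeded RNG
            for i in range(n - 1, 0, -1):
                j = int(np.random.random() * (i + 1))
                tmp = order[i]; order[i] = order[j]; order[j] = tmp
        loss_sum = 0.0
        loss_cnt = 0
        for bi in range(n_batches):
            s = bi * batch_size
            e = min(s + batch_size, n)
            B = e - s
            # gather batch (time order unless shuffled)
            Xb = np.empty((k, B, p), dtype=np.float32)
            yb = np.empty(B, dtype=np.float32)
            for ii in range(B):
                src = order[s + ii]
                yb[ii] = y[src]
                for t in range(k):
                    for j in range(p):
                        Xb[t, ii, j] = X[src, t, j]

            # ---- forward, caching per-step state ----
            # input projections for every timestep in one GEMM
            AX = np.dot(Xb.reshape(k * B, p), W)  # (k*B, 3h)
            Hs = np.zeros((k + 1, B, h), dtype=np.float32)
            Zs = np.empty((k, B, h), dtype=np.float32)
            Rs = np.empty((k, B, h), dtype=np.float32)
            Cs = np.empty((k, B, h), dtype=np.float32)
            Ds = np.empty((k, B, h), dtype=np.float32)
            RHs = np.empty((k, B, h), dtype=np.float32)
            for t in range(k):
                ax = AX[t * B : (t + 1) * B]  # (B, 3h) contiguous view
                hU = np.dot(Hs[t], U)  # (B, 2h)
                for i in range(B):
                    for j in range(h):
                        Zs[t, i, j] = _sigmoid(ax[i, j] + hU[i, j] + b[j])
                        Rs[t, i, j] = _sigmoid(ax[i, h + j] + hU[i, h + j] + b[h + j])
                        RHs[t, i, j] = Rs[t, i, j] * Hs[t, i, j]
                ac = np.dot(RHs[t], Uc)
                for i in range(B):
                    for j in range(h):
                        ac[i, j] = ac[i, j] + ax[i, 2 * h + j] + b[2 * h + j]
                _act_value_grad(ac, act_code, Cs[t], Ds[t])
                for i in range(B):
                    for j in range(h):
                        Hs[t + 1, i, j] = (
                            Zs[t, i, j] * Hs[t, i, j]
                            + (1.0 - Zs[t, i, j]) * Cs[t, i, j]
                        )

            # dropout on final state (inverted scaling), then dense output
            mask = np.empty((B, h), dtype=np.float32)
            hd = np.empty((B, h), dtype=np.float32)
            for i in range(B):
                for j in range(h):
                    if dropout > 0.0 and np.random.random() < dropout:
                        mask[i, j] = 0.0
                    else:
                        mask[i, j] = 1.0 / keep if dropout > 0.0 else 1.0
                    hd[i, j] = Hs[k, i, j] * mask[i, j]
            dy = np.empty(B, dtype=np.float32)
            batch_loss = 0.0
            for i in range(B):
                acc = bo[0]
                for j in range(h):
                    acc += hd[i, j] * Wo[j]
                resid = acc - yb[i]
                batch_loss += abs(resid)
                if resid > 0.0:
                    dy[i] = 1.0 / B
                elif resid < 0.0:
                    dy[i] = -1.0 / B
                else:
                    dy[i] = 0.0
            batch_loss /= B
            if not np.isfinite(batch_loss):
                return 1
            loss_sum += batch_loss * B
            loss_cnt += B

            # ---- backward ----
            gWo = np.zeros_like(Wo)
            gbo = np.zeros_like(bo)
            dh = np.empty((B, h), dtype=np.float32)
            for i in range(B):
                for j in range(h):
                    gWo[j] += hd[i, j] * dy[i]
                    dh[i, j] = dy[i] * Wo[j] * mask[i, j]
                gbo[0] += dy[i]
            # per-step gate gradients, stacked so the weight-gradient GEMMs
            # can run once over all timesteps
            DAs = np.empty((k, B, 3 * h), dtype=np.float32)
            for t in range(k - 1, -1, -1):
                DA = DAs[t]
                da_c = np.empty((B, h), dtype=np.float32)
                for i in range(B):
                    for j in range(h):
                        z = Zs[t, i, j]
                        hp = Hs[t, i, j]
                        c = Cs[t, i, j]
                        dz = dh[i, j] * (hp - c)
                        dcd = dh[i, j] * (1.0 - z)
                        da_c[i, j] = dcd * Ds[t, i, j]
                        DA[i, 2 * h + j] = da_c[i, j]
                        DA[i, j] = dz * z * (1.0 - z)  # da_z (dr term added below)
                        dh[i, j] = dh[i, j] * z  # start of dh_prev
                drh = np.dot(da_c, Uc.T)  # (B, h)
                for i in range(B):
                    for j in range(h):
                        r = Rs[t, i, j]
                        dr = drh[i, j] * Hs[t, i, j]
                        DA[i, h + j] = dr * r * (1.0 - r)  # da_r
                        dh[i, j] += drh[i, j] * r
                DA2 = DA[:, : 2 * h].copy()
                dhU = np.dot(DA2, U.T)  # (B, h)
                for i in range(B):
                    for j in range(h):
                        dh[i, j] += dhU[i, j]
            DA_all = DAs.reshape(k * B, 3 * h)
            gW = np.dot(Xb.reshape(k * B, p).T, DA_all)
            gU = np.dot(
                Hs[:k].copy().reshape(k * B, h).T, np.ascontiguousarray(DA_all[:, : 2 * h])
            )
            gUc = np.dot(RHs.reshape(k * B, h).T, np.ascontiguousarray(DA_all[:, 2 * h :]))
            gb = np.zeros_like(b)
            for row in range(k * B):
                for j in range(3 * h):
                    gb[j] += DA_all[row, j]

            adam_t += 1
            _adam_update(W, gW, mW, vW, adam_t, lr, b1, b2, eps)
            _adam_update(U, gU, mU, vU, adam_t, lr, b1, b2, eps)
            _adam_update(Uc, gUc, mUc, vUc, adam_t, lr, b1, b2, eps)
            _adam_update(b, gb, mb, vb, adam_t, lr, b1, b2, eps)
            _adam_update(Wo, gWo, mWo, vWo, adam_t, lr, b1, b2, eps)
            _adam_update(bo, gbo, mbo, vbo, adam_t, lr, b1, b2, eps)

        history[0, epoch] = loss_sum / loss_cnt
        if yval.shape[0] > 0:
            yv = gru_forward(Xval, W, U, Uc, b, Wo, bo, act_code)
            vsum = 0.0
            for i in range(yv.shape[0]):
                vsum += abs(yv[i] - yval[i])
            history[1, epoch] = vsum / yv.shape[0]
        else:
            history[1, epoch] = np.nan
        if not np.isfinite(history[0, epoch]):
            return 1
    return 0
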