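"""Numba kernels for the Gibbs/slice samplers.

Two chains live here: the bivariate Poisson phylogenetic mixed model and the
Pagel-lambda GLS regression. Both are written against a one-time spectral
decomposition of the phylogenetic covariance so every iteration costs
O(n^2) (two n x n matrix-vector products) plus O(n) scalar updates.

Blocking for the mixed model, with latent field l (n x 2), working
phylogenetic effects u, working scalars alpha (parameter expansion), and
G = diag(alpha) G_u diag(alpha):

  y_ik | l_ik            ~ Poisson(exp(l_ik))            [slice update of l]
  l_i. | beta, a, R      ~ N2(x_i' beta + a_i., R)       [Gaussian layer]
  a = alpha * u,  vec(u) ~ N(0, G_u kron A)              [2x2 blocks in the
                                                          eigenbasis of A]
  beta                   ~ N(0, v_f I)                   [conjugate joint]
  G_u ~ IW(V_G, nu_G),  alpha ~ N2(a_mu, a_V),  R ~ IW(V_R, nu_R)

The latent value is clipped to [-30, 30] inside exp(); clip events are
counted and surfaced to the caller.
"""

import numpy as np
from numba import njit

CLIP = 30.0


@njit(cache=True)
def _inv2(M):
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    out = np.empty((2, 2))
    out[0, 0] = M[1, 1] / det
    out[1, 1] = M[0, 0] / det
    out[0, 1] = -M[0, 1] / det
    out[1, 0] = -M[1, 0] / det
    return out


@njit(cache=True)
def _rand_invwishart2(scale, df):
    """Draw Sigma ~ IW(scale, df) for d=2 via Bartlett on Sigma^{-1}."""
    V = _inv2(scale)  # Sigma^{-1} ~ Wishart(scale^{-1}, df)
    L00 = np.sqrt(V[0, 0])
    L10 = V[1, 0] / L00
    L11 = np.sqrt(V[1, 1] - L10 * L10)
    A00 = np.sqrt(np.random.gamma(df / 2.0, 2.0))
    A11 = np.sqrt(np.random.gamma((df - 1.0) / 2.0, 2.0))
    A10 = np.random.standard_normal()
    B00 = L00 * A00
    B10 = L10 * A00 + L11 * A10
    B11 = L11 * A11
    W = np.empty((2, 2))
    W[0, 0] = B00 * B00
    W[0, 1] = B00 * B10
    W[1, 0] = W[0, 1]
    W[1, 1] = B10 * B10 + B11 * B11
    return _inv2(W)


@njit(cache=True)
def _logf_pois(lv, yv, m, v):
    e = lv
    if e > CLIP:
        e = CLIP
    elif e < -CLIP:
        e = -CLIP
    return yv * lv - np.exp(e) - 0.5 * (lv - m) * (lv - m) / v


@njit(cache=True)
def _slice_pois(l0, yv, m, v):
    """One slice-sampling update of a latent Poisson log-mean with a normal prior."""
    logy = _logf_pois(l0, yv, m, v) + np.log(np.random.random())
    w = 1.0 + np.sqrt(v)
    left = l0 - np.random.random() * w
    right = left + w
    for _ in range(64):
        if _logf_pois(left, yv, m, v) <= logy:
            break
        left -= w
    for _ in range(64):
        if _logf_pois(right, yv, m, v) <= logy:
            break
        right += w
    for _ in range(128):
        x = left + np.random.random() * (right - left)
        if _logf_pois(x, yv, m, v) >= logy:
            return x
        if x < l0:
            left = x
        else:
            right = x
    return l0


@njit(cache=True)
def run_mpglmm_chain(y, X, XtX, U, d,
                     v_f, Vg, nu_g, a_mu, a_V, Vr, nu_r,
                     n_iter, burn_in, thin, seed,
                     l, beta, ut, alpha, Gu, R):
    """Run one MCMC chain; returns retained draws and the clip count.

    y: (n,2) counts; X: (n,p) fixed-effect columns (shared by both traits);
    U, d: eigenvectors/values of the phylogenetic covariance A; remaining
    arguments are prior hyperparameters, chain settings, and initial state
    (modified in place).
    """
    np.random.seed(seed)
    n = y.shape[0]
    p = X.shape[1]
    n_keep = (n_iter - burn_in) // thin
    beta_out = np.empty((n_keep, 2 * p))
    G_out = np.empty((n_keep, 2, 2))
    R_out = np.empty((n_keep, 2, 2))
    a_out = np.empty((n_keep, n, 2))
    e_out = np.empty((n_keep, n, 2))
    n_clip = 0
    kept = 0

    XB = np.empty((n, 2))
    for k in range(2):
        for i in range(n):
            s = 0.0
            for j in range(p):
                s += X[i, j] * beta[k * p + j]
            XB[i, k] = s
    u = U @ ut
    a = np.empty((n, 2))
    for i in range(n):
        a[i, 0] = alpha[0] * u[i, 0]
        a[i, 1] = alpha[1] * u[i, 1]

    a_V_inv = _inv2(a_V)
    B = np.empty((2 * p, 2 * p))
    rhs = np.empty(2 * p)

    for it in range(n_iter):
        Rinv = _inv2(R)
        Gu_inv = _inv2(Gu)

        # --- latent field l: univariate slice updates, trait conditionals via R
        for i in range(n):
            for k in range(2):
                kk = 1 - k
                mu_k = XB[i, k] + a[i, k]
                mu_kk = XB[i, kk] + a[i, kk]
                c = R[k, kk] / R[kk, kk]
                m = mu_k + c * (l[i, kk] - mu_kk)
                v = R[k, k] - c * R[k, kk]
                if v < 1e-12:
                    v = 1e-12
                l[i, k] = _slice_pois(l[i, k], y[i, k], m, v)
                if l[i, k] > CLIP or l[i, k] < -CLIP:
                    n_clip += 1

        # --- phylogenetic working effects u (2x2 blocks in eigenbasis of A)
        resid = l - XB
        t = U.T @ resid
        Su = np.zeros((2, 2))
        for j in range(n):
            P00 = Gu_inv[0, 0] / d[j] + alpha[0] * alpha[0] * Rinv[0, 0]
            P01 = Gu_inv[0, 1] / d[j] + alpha[0] * alpha[1] * Rinv[0, 1]
            P11 = Gu_inv[1, 1] / d[j] + alpha[1] * alpha[1] * Rinv[1, 1]
            det = P00 * P11 - P01 * P01
            r0 = alpha[0] * (Rinv[0, 0] * t[j, 0] + Rinv[0, 1] * t[j, 1])
            r1 = alpha[1] * (Rinv[1, 0] * t[j, 0] + Rinv[1, 1] * t[j, 1])
            m0 = (P11 * r0 - P01 * r1) / det
            m1 = (P00 * r1 - P01 * r0) / det
            # sample from N(m, P^{-1}) via chol of P^{-1}
            c00 = np.sqrt(P11 / det)
            c10 = -P01 / det / c00
            c11 = np.sqrt(P00 / det - c10 * c10)
            z0 = np.random.standard_normal()
            z1 = np.random.standard_normal()
            ut[j, 0] = m0 + c00 * z0
            ut[j, 1] = m1 + c10 * z0 + c11 * z1
            Su[0, 0] += ut[j, 0] * ut[j, 0] / d[j]
            Su[0, 1] += ut[j, 0] * ut[j, 1] / d[j]
            Su[1, 1] += ut[j, 1] * ut[j, 1] / d[j]
        Su[1, 0] = Su[0, 1]
        u = U @ ut

        # --- G_u: conjugate inverse-Wishart
        Gu = _rand_invwishart2(Vg + Su, nu_g + n)

        # --- working scalars alpha (parameter expansion for G)
        P00 = a_V_inv[0, 0]
        P01 = a_V_inv[0, 1]
        P11 = a_V_inv[1, 1]
        r0 = a_V_inv[0, 0] * a_mu[0] + a_V_inv[0, 1] * a_mu[1]
        r1 = a_V_inv[1, 0] * a_mu[0] + a_V_inv[1, 1] * a_mu[1]
        for i in range(n):
            P00 += Rinv[0, 0] * u[i, 0] * u[i, 0]
            P01 += Rinv[0, 1] * u[i, 0] * u[i, 1]
            P11 += Rinv[1, 1] * u[i, 1] * u[i, 1]
            r0 += u[i, 0] * (Rinv[0, 0] * resid[i, 0] + Rinv[0, 1] * resid[i, 1])
            r1 += u[i, 1] * (Rinv[1, 0] * resid[i, 0] + Rinv[1, 1] * resid[i, 1])
        det = P00 * P11 - P01 * P01
        m0 = (P11 * r0 - P01 * r1) / det
        m1 = (P00 * r1 - P01 * r0) / det
        c00 = np.sqrt(P11 / det)
        c10 = -P01 / det / c00
        c11 = np.sqrt(P00 / det - c10 * c10)
        z0 = np.random.standard_normal()
        z1 = np.random.standard_normal()
        alpha[0] = m0 + c00 * z0
        alpha[1] = m1 + c10 * z0 + c11 * z1
        for i in range(n):
            a[i, 0] = alpha[0] * u[i, 0]
            a[i, 1] = alpha[1] * u[i, 1]

        # --- fixed effects beta: joint Gaussian across both traits
        for kb in range(2):
            for jb in range(2):
                for r_ in range(p):
                    for c_ in range(p):
                        B[kb * p + r_, jb * p + c_] = Rinv[kb, jb] * XtX[r_, c_]
        for j in range(2 * p):
            B[j, j] += 1.0 / v_f
        for kb in range(2):
            for r_ in range(p):
                s = 0.0
                for i in range(n):
                    ra = l[i, 0] - a[i, 0]
                    rb = l[i, 1] - a[i, 1]
                    s += X[i, r_] * (Rinv[kb, 0] * ra + Rinv[kb, 1] * rb)
                rhs[kb * p + r_] = s
        Lb = np.linalg.cholesky(B)
        m = np.linalg.solve(B, rhs)
        z = np.random.standard_normal(2 * p)
        beta = m + np.linalg.solve(Lb.T, z)
        for k in range(2):
            for i in range(n):
                s = 0.0
                for j in range(p):
                    s += X[i, j] * beta[k * p + j]
                XB[i, k] = s

        # --- residual covariance R
        SS = np.zeros((2, 2))
        for i in range(n):
            e0 = l[i, 0] - XB[i, 0] - a[i, 0]
            e1 = l[i, 1] - XB[i, 1] - a[i, 1]
            SS[0, 0] += e0 * e0
            SS[0, 1] += e0 * e1
            SS[1, 1] += e1 * e1
        SS[1, 0] = SS[0, 1]
        R = _rand_invwishart2(Vr + SS, nu_r + n)

        # --- retain
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            for j in range(2 * p):
                beta_out[kept, j] = beta[j]
            G_out[kept, 0, 0] = alpha[0] * alpha[0] * Gu[0, 0]
            G_out[kept, 0, 1] = alpha[0] * alpha[1] * Gu[0, 1]
            G_out[kept, 1, 0] = G_out[kept, 0, 1]
            G_out[kept, 1, 1] = alpha[1] * alpha[1] * Gu[1, 1]
            R_out[kept] = R
            for i in range(n):
                a_out[kept, i, 0] = a[i, 0]
                a_out[kept, i, 1] = a[i, 1]
                e_out[kept, i, 0] = l[i, 0] - XB[i, 0] - a[i, 0]
                e_out[kept, i, 1] = l[i, 1] - XB[i, 1] - a[i, 1]
            kept += 1

    return beta_out[:kept], G_out[:kept], R_out[:kept], a_out[:kept], e_out[:kept], n_clip


@njit(cache=True)
def _pgls_loglam(lam, ev, r2, sigma2):
    s = 0.0
    for j in range(ev.shape[0]):
        wj = 1.0 + lam * (ev[j] - 1.0)
        s += -0.5 * np.log(wj) - 0.5 * r2[j] / (wj * sigma2)
    return s


@njit(cache=True)
def run_pgls_chain(yt, Xt, ev, v_b, ig_a, ig_b,
                   n_iter, burn_in, thin, seed):
    """Gibbs/slice chain for y = Xb + eps, eps ~ N(0, sigma2 V(lambda)).

    yt, Xt are the response and design pre-whitened by D^{-1/2} and rotated
    into the eigenbasis of the depth-normalised covariance, so V(lambda)
    is diagonal with entries 1 + lambda (ev_j - 1). Priors: b ~ N(0, v_b I),
    sigma2 ~ InvGamma(ig_a, ig_b), lambda ~ Uniform(0, 1).
    """
    np.random.seed(seed)
    n, p = Xt.shape
    n_keep = (n_iter - burn_in) // thin
    b_out = np.empty((n_keep, p))
    s2_out = np.empty(n_keep)
    lam_out = np.empty(n_keep)
    kept = 0

    b = np.zeros(p)
    # OLS-ish start
    s2 = np.var(yt) + 1e-8
    lam = 0.5

    P = np.empty((p, p))
    rhs = np.empty(p)
    r2 = np.empty(n)

    for it in range(n_iter):
        # weights
        w = np.empty(n)
        for j in range(n):
            w[j] = 1.0 / (1.0 + lam * (ev[j] - 1.0))

        # b | sigma2, lambda
        for r_ in range(p):
            rhs[r_] = 0.0
            for c_ in range(p):
                P[r_, c_] = 0.0
        for j in range(n):
            for r_ in range(p):
                rhs[r_] += Xt[j, r_] * w[j] * yt[j] / s2
                for c_ in range(p):
                    P[r_, c_] += Xt[j, r_] * w[j] * Xt[j, c_] / s2
        for r_ in range(p):
            P[r_, r_] += 1.0 / v_b
        Lp = np.linalg.cholesky(P)
        m = np.linalg.solve(P, rhs)
        z = np.random.standard_normal(p)
        b = m + np.linalg.solve(Lp.T, z)

        # residuals in the eigenbasis
        for j in range(n):
            s = yt[j]
            for c_ in range(p):
                s -= Xt[j, c_] * b[c_]
            r2[j] = s * s

        # sigma2 | b, lambda
        ssw = 0.0
        for j in range(n):
            ssw += w[j] * r2[j]
        s2 = (ig_b + 0.5 * ssw) / np.random.gamma(ig_a + 0.5 * n, 1.0)

        # lambda | b, sigma2 : slice within [0, 1]
        logy = _pgls_loglam(lam, ev, r2, s2) + np.log(np.random.random())
        left = 0.0
        right = 1.0
        for _ in range(128):
            x = left + np.random.random() * (right - left)
            if _pgls_loglam(x, ev, r2, s2) >= logy:
                lam = x
                break
            if x < lam:
                left = x
            else:
                right = x

        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            for c_ in range(p):
                b_out[kept, c_] = b[c_]
            s2_out[kept] = s2
            lam_out[kept] = lam
            kept += 1

    return b_out[:kept], s2_out[:kept], lam_out[:kept]
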