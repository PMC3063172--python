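"""Constrained mixture-of-Gaussians tissue segmentation.

Models the T2* intensity distribution as a prior-weighted mixture of
Gaussians with six tissue classes (GWM 3, CSF 2, CMB 2, skull 3, scalp 2,
other 4 components by default) and a smooth multiplicative bias field.
Parameters are estimated by EM; after every M-step the class means are
projected onto the constraint set that encodes the T2* histogram ordering:

* every CSF component mean stays above the mean of the GWM Gaussians
  (CSF is bright on T2*), and
* every CMB component mean stays below 50% of the GWM mean (microbleeds
  are markedly hypointense), which confines the search for microbleeds to
  the dark half of the histogram.

The bias field is a low-order 3D polynomial in log-intensity, refitted by
weighted least squares inside the EM loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Volume3D
from .priors import CLASS_NAMES, TissuePriorSet

DEFAULT_N_GAUSSIANS = {
    "gwm": 3,
    "csf": 2,
    "cmb": 2,
    "skull": 3,
    "scalp": 2,
    "other": 4,
}

_LOG_FLOOR = 1e-30


def _estep_numpy(ycorr, y2corr, log_prior_t, comp_class, A, B, C, R):
    """Responsibilities R (n_vox, K) and EM sufficient statistics.

    log p_k(x) = log prior_class + log w + logN(y; mu, var), evaluated in
    the quadratic form A*y^2 + B*y + C, softmax-normalised per voxel.
    ``log_prior_t`` is (n_vox, n_class).  Returns (Rs, Ry, Ryy, loglik)."""
    K = len(comp_class)
    for c in range(K):
        np.multiply(y2corr, A[c], out=R[:, c])
        R[:, c] += B[c] * ycorr
        R[:, c] += C[c]
        R[:, c] += log_prior_t[:, comp_class[c]]
    m = R.max(axis=1)
    R -= m[:, None]
    np.exp(R, out=R)
    S = R.sum(axis=1)
    ll = float(np.sum(np.log(np.maximum(S, _LOG_FLOOR)) + m))
    R /= np.maximum(S, _LOG_FLOOR)[:, None]
    Rs = R.sum(axis=0, dtype=np.float64)
    Ry = (ycorr @ R).astype(np.float64)
    Ryy = (y2corr @ R).astype(np.float64)
    return Rs, Ry, Ryy, ll


try:  # single-pass fused kernel; the numpy path is the reference
    import numba as _numba

    @_numba.njit(cache=True, fastmath=True)
    def _estep_numba(ycorr, y2corr, log_prior_t, comp_class, A, B, C, R):
        # log_prior_t is (n_vox, n_class) for cache locality
        n_vox, K = R.shape
        Rs = np.zeros(K, np.float64)
        Ry = np.zeros(K, np.float64)
        Ryy = np.zeros(K, np.float64)
        ll = 0.0
        logp = np.empty(K, np.float32)
        for i in range(n_vox):
            m = np.float32(-1e30)
            yi = ycorr[i]
            y2i = y2corr[i]
            for c in range(K):
                v = (
                    log_prior_t[i, comp_class[c]]
                    + C[c]
                    + B[c] * yi
                    + A[c] * y2i
                )
                logp[c] = v
                if v > m:
                    m = v
            s = np.float32(0.0)
            for c in range(K):
                d = logp[c] - m
                # contributions below exp(-15) ~ 3e-7 are negligible
                e = np.exp(d) if d > np.float32(-15.0) else np.float32(0.0)
                logp[c] = e
                s += e
            ll += np.log(s) + m
            inv = np.float32(1.0) / s
            for c in range(K):
                e = logp[c]
                if e > np.float32(0.0):
                    r = e * inv
                    R[i, c] = r
                    Rs[c] += r
                    Ry[c] += r * ycorr[i]
                    Ryy[c] += r * y2corr[i]
                else:
                    R[i, c] = np.float32(0.0)
        return Rs, Ry, Ryy, ll

    def _estep_dispatch(ycorr, y2corr, log_prior_t, comp_class, A, B, C, R):
        Rs, Ry, Ryy, ll = _estep_numba(
            ycorr,
            y2corr,
            np.ascontiguousarray(log_prior_t),
            np.ascontiguousarray(comp_class),
            A,
            B,
            C,
            R,
        )
        return Rs, Ry, Ryy, float(ll)

except Exception:  # pragma: no cover - numba not installed
    _estep_dispatch = _estep_numpy


@dataclass
class EMConfig:
    n_gaussians: dict = field(default_factory=lambda: dict(DEFAULT_N_GAUSSIANS))
    tol: float = 1e-5  # relative log-likelihood change
    max_iter: int = 100
    eps: float = 1e-3  # margin used by the constraint projection
    variance_floor_frac: float = 0.01  # fraction of the in-brain range
    bias: bool = True
    bias_order: int = 3
    # the field is refitted only once the mixture has nearly converged at
    # the current field (estimate -> correct -> refit), at most this many
    # times; per-iteration coupling of field and mixture is unstable
    max_bias_refits: int = 4
    bias_settle_factor: float = 100.0  # "nearly converged" = factor * tol
    cmb_init_percentiles: tuple = (2.0, 10.0)
    # parameter-estimation lattice: every ``sampling_step``-th voxel per
    # axis (3 mm sampling at the 1.5 mm working grid); posteriors are
    # always produced on the full grid
    sampling_step: int = 2


@dataclass
class MixtureModel:
    """Fitted per-class Gaussian components plus constraint metadata."""

    class_names: tuple
    n_gaussians: dict
    means: dict
    variances: dict
    weights: dict  # within-class mixing weights, summing to 1 per class
    loglik_trace: list = field(default_factory=list)
    projection_events: list = field(default_factory=list)
    bias_events: list = field(default_factory=list)
    collapsed_classes: list = field(default_factory=list)
    converged: bool = False

    def mean_gwm(self) -> float:
        """Mixing-weight-weighted mean of the GWM Gaussians."""
        w = np.asarray(self.weights["gwm"], float)
        return float(np.sum(w * np.asarray(self.means["gwm"], float)) / w.sum())

    def copy(self) -> "MixtureModel":
        return MixtureModel(
            class_names=self.class_names,
            n_gaussians=dict(self.n_gaussians),
            means={k: np.array(v) for k, v in self.means.items()},
            variances={k: np.array(v) for k, v in self.variances.items()},
            weights={k: np.array(v) for k, v in self.weights.items()},
            loglik_trace=list(self.loglik_trace),
            projection_events=list(self.projection_events),
            bias_events=list(self.bias_events),
            collapsed_classes=list(self.collapsed_classes),
            converged=self.converged,
        )

    def to_dict(self) -> dict:
        return {
            "classes": list(self.class_names),
            "n_gaussians": {k: int(v) for k, v in self.n_gaussians.items()},
            "means": {k: np.asarray(v).tolist() for k, v in self.means.items()},
            "variances": {
                k: np.asarray(v).tolist() for k, v in self.variances.items()
            },
            "weights": {
                k: np.asarray(v).tolist() for k, v in self.weights.items()
            },
            "loglik_trace": [float(x) for x in self.loglik_trace],
            "converged": bool(self.converged),
        }


@dataclass
class PosteriorMaps:
    """Per-class posterior probability volumes (sum 1 per voxel)."""

    maps: dict
    affine: np.ndarray

    def stack(self) -> np.ndarray:
        return np.stack([self.maps[k] for k in self.maps])

    def as_volume(self, name: str) -> Volume3D:
        return Volume3D(self.maps[name].astype(np.float32), self.affine.copy())


@dataclass
class BiasField:
    """Smooth multiplicative intensity field exp(polynomial)."""

    coefficients: np.ndarray
    order: int
    field: Volume3D

    @property
    def data(self) -> np.ndarray:
        return self.field.data


def polynomial_basis_flat(shape, order: int) -> np.ndarray:
    """Monomial basis up to total degree ``order`` on [-1, 1]^3 coordinates,
    flattened to (n_terms, n_voxels) float32."""
    coords = [
        (2.0 * np.arange(n) / max(n - 1, 1) - 1.0).astype(np.float32)
        for n in shape
    ]
    X = coords[0][:, None, None]
    Y = coords[1][None, :, None]
    Z = coords[2][None, None, :]
    terms = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                terms.append(
                    np.broadcast_to(
                        (X**i) * (Y**j) * (Z**k), shape
                    ).reshape(-1)
                )
    return np.stack(terms).astype(np.float32)


def constrain_means(model: MixtureModel, eps: float = 1e-3) -> MixtureModel:
    """Project class means onto the T2* ordering constraints.

    CSF means at or below the GWM mean are clipped just above it; CMB means
    at or above half the GWM mean are clipped just below that bound.  A
    model already satisfying both constraints is returned unchanged.
    """
    out = model.copy()
    m_gwm = out.mean_gwm()
    changed = False
    if "csf" in out.means:
        mu = np.asarray(out.means["csf"], float)
        bad = mu <= m_gwm
        if np.any(bad):
            mu[bad] = m_gwm * (1.0 + eps)
            out.means["csf"] = mu
            changed = True
    if "cmb" in out.means:
        mu = np.asarray(out.means["cmb"], float)
        bound = 0.5 * m_gwm
        bad = mu >= bound
        if np.any(bad):
            mu[bad] = bound * (1.0 - eps)
            out.means["cmb"] = mu
            changed = True
    out._projection_changed = changed
    return out


def _weighted_quantile(sorted_y, cum_w, q) -> float:
    total = cum_w[-1]
    if total <= 0:
        return float(sorted_y[len(sorted_y) // 2])
    return float(np.interp(q * total, cum_w, sorted_y))


def _init_model(
    y: np.ndarray,
    prior_stack: np.ndarray,
    class_names,
    n_gaussians: dict,
    brain: np.ndarray,
    config: EMConfig,
) -> MixtureModel:
    """Deterministic initialisation from prior-weighted intensity quantiles;
    the CMB components start at low in-brain percentiles (dark voxels)."""
    order = np.argsort(y, kind="stable")
    ys = y[order]
    yb = y[brain] if brain.any() else y
    p1, p99 = np.percentile(yb, [1, 99])
    spread = float(p99 - p1)
    if spread <= 0:
        spread = max(abs(float(np.mean(yb))), 1.0)
    var0 = (0.1 * spread) ** 2
    means, variances, weights = {}, {}, {}
    for ci, name in enumerate(class_names):
        n = int(n_gaussians[name])
        if name == "cmb":
            lo, hi = config.cmb_init_percentiles
            pct = np.linspace(lo, hi, n)
            mu = np.percentile(yb, pct)
        else:
            cw = np.cumsum(prior_stack[ci][order].astype(np.float64))
            qs = (np.arange(n) + 0.5) / n
            mu = np.array([_weighted_quantile(ys, cw, q) for q in qs])
        means[name] = np.asarray(mu, float)
        variances[name] = np.full(n, var0)
        weights[name] = np.full(n, 1.0 / n)
    model = MixtureModel(
        class_names=tuple(class_names),
        n_gaussians=dict(n_gaussians),
        means=means,
        variances=variances,
        weights=weights,
    )
    return model


def _fit_em(
    y: np.ndarray,
    prior_stack: np.ndarray,
    class_names,
    n_gaussians: dict,
    brain: np.ndarray,
    config: EMConfig,
    shape,
    init_model: MixtureModel | None = None,
    apply_constraints: bool = True,
):
    """Prior-weighted EM on flattened arrays.  Returns (model, R_class,
    bias_log_field_flat, basis)."""
    y = np.asarray(y, np.float32)
    n_vox = y.size
    yb = y[brain] if brain.any() else y
    p1, p99 = np.percentile(yb, [1, 99])
    spread = float(p99 - p1)
    if spread <= 0:
        spread = max(abs(float(np.mean(yb))), 1.0)
    var_floor = (config.variance_floor_frac * spread) ** 2

    model = (
        init_model.copy()
        if init_model is not None
        else _init_model(y, prior_stack, class_names, n_gaussians, brain, config)
    )
    model.loglik_trace = []
    model.projection_events = []
    model.bias_events = []
    model.converged = False  # a warm start must not inherit the flag
    if apply_constraints:
        model = constrain_means(model, config.eps)

    comp_class = []
    for ci, name in enumerate(class_names):
        comp_class += [ci] * int(n_gaussians[name])
    comp_class = np.asarray(comp_class)
    K = len(comp_class)

    log_prior = np.log(np.maximum(prior_stack, _LOG_FLOOR)).astype(np.float32)

    basis = None
    coeff = None
    if config.bias:
        basis = polynomial_basis_flat(shape, config.bias_order)

    # parameters are estimated on a decimated voxel lattice (the standard
    # sampling-distance device of unified segmentation); posteriors are
    # always computed on the full grid afterwards
    step = max(int(config.sampling_step), 1)
    if step > 1:
        sel = np.zeros(shape, bool)
        sel[::step, ::step, ::step] = True
        sel = sel.reshape(-1)
    else:
        sel = np.ones(n_vox, bool)
    y_f = np.ascontiguousarray(y[sel])
    log_prior_f_t = np.ascontiguousarray(log_prior[:, sel].T)
    brain_f = brain[sel]
    basis_f = None if basis is None else np.ascontiguousarray(basis[:, sel])
    n_fit = y_f.size
    log_b = np.zeros(n_fit, np.float32)

    def flat_params():
        mus, vars_, ws = [], [], []
        for name in class_names:
            mus += list(model.means[name])
            vars_ += list(model.variances[name])
            ws += list(model.weights[name])
        return (
            np.asarray(mus, np.float32),
            np.maximum(np.asarray(vars_, np.float32), var_floor),
            np.asarray(ws, np.float32),
        )

    def e_step(R, ycorr, y2corr, mus, vars_, ws):
        """Fill R (n_vox, K) with responsibilities; returns the sufficient
        statistics and the data log-likelihood (without the bias Jacobian
        term)."""
        A = (-0.5 / vars_).astype(np.float32)
        B = (mus / vars_).astype(np.float32)
        C = (
            np.log(np.maximum(ws, _LOG_FLOOR))
            - 0.5 * np.log(2.0 * np.pi * vars_)
            - 0.5 * mus**2 / vars_
        ).astype(np.float32)
        return _estep_dispatch(ycorr, y2corr, lp, comp_class, A, B, C, R)

    ycorr = y_f.copy()
    y2corr = ycorr * ycorr
    R = np.empty((n_fit, K), np.float32)
    lp = log_prior_f_t
    prev_ll = -np.inf
    bias_refits = 0
    for it in range(config.max_iter):
        mus, vars_, ws = flat_params()
        # E-step: responsibilities proportional to prior * w * N(y/b; mu, var)
        Rs, Ry, Ryy, ll = e_step(R, ycorr, y2corr, mus, vars_, ws)
        ll -= float(np.sum(log_b))
        model.loglik_trace.append(ll)

        rel_change = abs(ll - prev_ll) / max(abs(ll), 1.0)
        settled = it >= 1 and rel_change < config.bias_settle_factor * config.tol
        want_bias = (
            config.bias
            and bias_refits < config.max_bias_refits
            and settled
            and brain_f.sum() > basis_f.shape[0] * 4
        )
        if it >= 1 and rel_change < config.tol and not want_bias:
            model.converged = True
            break
        prev_ll = ll

        # M-step from the accumulated sufficient statistics
        new_mu = np.where(Rs > 1.0, Ry / np.maximum(Rs, 1e-12), mus)
        new_var = np.where(
            Rs > 1.0,
            np.maximum(
                Ryy / np.maximum(Rs, 1e-12) - new_mu**2, var_floor
            ),
            vars_,
        )
        collapsed = Rs <= 1.0
        pos = 0
        for name in class_names:
            n = int(n_gaussians[name])
            sl = slice(pos, pos + n)
            cls_total = Rs[sl].sum()
            model.means[name] = np.asarray(new_mu[sl], float)
            model.variances[name] = np.asarray(new_var[sl], float)
            if cls_total > 1.0:
                model.weights[name] = np.maximum(Rs[sl] / cls_total, 1e-8)
                model.weights[name] /= model.weights[name].sum()
            elif name not in model.collapsed_classes:
                model.collapsed_classes.append(name)
            if np.any(collapsed[sl]) and name not in model.collapsed_classes:
                model.collapsed_classes.append(name)
            pos += n

        if apply_constraints:
            model = constrain_means(model, config.eps)
            if getattr(model, "_projection_changed", False):
                model.projection_events.append(it)

        # bias update: WLS fit of the log-residual on the polynomial basis
        if want_bias:
            bias_refits += 1
            mus2, vars2, _ = flat_params()
            valid = mus2 > 1e-3 * spread
            log_mu = np.log(np.maximum(mus2, _LOG_FLOOR)).astype(np.float32)
            # precision of log y within a component is mu^2 / sigma^2;
            # precision weighting suppresses partial-volume components,
            # whose broad variances would otherwise bend the field
            prec = (mus2[valid] ** 2 / vars2[valid]).astype(np.float32)
            Rb = R[brain_f][:, valid] * prec
            w_vox = Rb.sum(axis=1)
            yb_obs = np.maximum(y_f[brain_f], 1e-3 * spread)
            target = (
                Rb @ (-log_mu[valid]) + w_vox * np.log(yb_obs)
            ) / np.maximum(w_vox, 1e-6)
            B = basis_f[:, brain_f]
            Bw = B * w_vox
            A = Bw @ B.T
            rhs = Bw @ target
            lam = 1e-3 * max(np.trace(A), 1.0) / A.shape[0]
            try:
                new_coeff = np.linalg.solve(A + lam * np.eye(A.shape[0]), rhs)
            except np.linalg.LinAlgError:
                new_coeff = coeff if coeff is not None else np.zeros(B.shape[0])
                warnings.warn("bias basis ill-conditioned; keeping field")
            new_log_b = (basis_f.T @ new_coeff.astype(np.float32)).astype(
                np.float32
            )
            new_log_b -= new_log_b[brain_f].mean()
            np.clip(new_log_b, -1.5, 1.5, out=new_log_b)
            delta = float(np.abs(new_log_b - log_b).max())
            if delta > 1e-6:
                model.bias_events.append(it)
            coeff = new_coeff
            log_b = new_log_b
            ycorr = y_f * np.exp(-log_b)
            y2corr = ycorr * ycorr
    else:
        tr = model.loglik_trace
        last = abs(tr[-1] - tr[-2]) / max(abs(tr[-1]), 1.0) if len(tr) > 1 else float("nan")
        warnings.warn(
            f"EM did not converge in {config.max_iter} iterations "
            f"(last relative change {last:.3g}); returning the best state"
        )

    # final posteriors on the full grid (the loop ran on the fit lattice);
    # realise the bias field everywhere from its coefficients
    if coeff is not None:
        log_b_full = (basis.T @ coeff.astype(np.float32)).astype(np.float32)
        brain_full = brain if brain.any() else np.ones(n_vox, bool)
        log_b_full -= log_b_full[brain_full].mean()
        np.clip(log_b_full, -1.5, 1.5, out=log_b_full)
    else:
        log_b_full = np.zeros(n_vox, np.float32)
    if step > 1 or not model.converged:
        ycorr_full = y * np.exp(-log_b_full)
        R = np.empty((n_vox, K), np.float32)
        lp = np.ascontiguousarray(log_prior.T)
        mus, vars_, ws = flat_params()
        e_step(R, ycorr_full, ycorr_full * ycorr_full, mus, vars_, ws)
    n_class = len(class_names)
    R_class = np.empty((n_class, n_vox), np.float64)
    for ci in range(n_class):
        R_class[ci] = R[:, comp_class == ci].sum(axis=1, dtype=np.float64)
    R_class /= np.maximum(R_class.sum(axis=0), _LOG_FLOOR)
    return model, R_class, log_b_full, coeff


def fit_constrained_mixture(
    vol: Volume3D,
    priors: TissuePriorSet,
    config: EMConfig | None = None,
    init_model: MixtureModel | None = None,
) -> tuple[MixtureModel, PosteriorMaps, BiasField]:
    """Fit the six-class constrained mixture to a T2* volume.

    Returns the fitted model, per-class posterior maps (summed over each
    class's Gaussians, renormalised per voxel) and the estimated bias
    field.
    """
    config = config or EMConfig()
    if tuple(vol.shape) != tuple(priors.shape):
        raise ValueError("volume and priors are on different grids")
    if priors.brain_mask.sum() <= 100:
        raise ValueError("brain mask too small (need > 100 voxels)")
    y = np.asarray(vol.data, np.float32).reshape(-1)
    prior_stack = priors.stack().reshape(len(CLASS_NAMES), -1).astype(np.float32)
    brain = priors.brain_mask.reshape(-1)
    model, R_class, log_b, coeff = _fit_em(
        y,
        prior_stack,
        CLASS_NAMES,
        config.n_gaussians,
        brain,
        config,
        vol.shape,
        init_model=init_model,
    )
    post = PosteriorMaps(
        maps={
            name: R_class[ci].reshape(vol.shape)
            for ci, name in enumerate(CLASS_NAMES)
        },
        affine=vol.affine.copy(),
    )
    field = Volume3D(
        np.exp(log_b).reshape(vol.shape).astype(np.float32),
        vol.affine.copy(),
        "bias field",
    )
    n_terms = (
        polynomial_basis_flat((1, 1, 1), config.bias_order).shape[0]
        if config.bias
        else 1
    )
    bias = BiasField(
        coefficients=(
            np.zeros(n_terms) if coeff is None else np.asarray(coeff, float)
        ),
        order=config.bias_order if config.bias else 0,
        field=field,
    )
    return model, post, bias


def estimate_bias(
    vol: Volume3D,
    posteriors: PosteriorMaps,
    model: MixtureModel,
    order: int = 3,
    brain_mask: np.ndarray | None = None,
) -> BiasField:
    """One precision-weighted least-squares bias fit at fixed posteriors.

    Within-class component responsibilities are reconstructed from the
    class posteriors (the within-class split depends only on the component
    likelihoods), each component's log-residual is weighted by its
    precision mu^2/sigma^2, and the aggregate residual is regressed on a
    polynomial basis.  The exponentiated field is mean-centred in log over
    the brain.
    """
    shape = vol.shape
    y = np.asarray(vol.data, np.float32).reshape(-1)
    names = list(posteriors.maps)
    brain = (
        np.ones(y.size, bool)
        if brain_mask is None
        else np.asarray(brain_mask, bool).reshape(-1)
    )
    spread = float(np.ptp(y[brain])) or 1.0
    basis = polynomial_basis_flat(shape, order)
    yb = y[brain]
    log_yb = np.log(np.maximum(yb, 1e-3 * spread))
    w_vox = np.zeros(yb.size, np.float64)
    num = np.zeros(yb.size, np.float64)
    for name in names:
        mu = np.asarray(model.means[name], float)
        var = np.asarray(model.variances[name], float)
        w = np.asarray(model.weights[name], float)
        keep = mu > 1e-3 * spread
        if not keep.any():
            continue
        mu, var, w = mu[keep], var[keep], w[keep]
        # within-class responsibilities at fixed parameters
        lg = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (yb[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        lg -= lg.max(axis=1, keepdims=True)
        r_in = np.exp(lg)
        r_in /= r_in.sum(axis=1, keepdims=True)
        p_cls = posteriors.maps[name].reshape(-1)[brain]
        prec = mu**2 / var
        rp = (p_cls[:, None] * r_in) * prec[None, :]
        w_vox += rp.sum(axis=1)
        num += rp @ np.log(mu)
    target = log_yb - num / np.maximum(w_vox, 1e-9)
    B = basis[:, brain]
    w_vox = w_vox.astype(np.float32)
    Bw = B * w_vox
    A = Bw @ B.T
    lam = 1e-3 * max(np.trace(A), 1.0) / A.shape[0]
    try:
        coeff = np.linalg.solve(
            A + lam * np.eye(A.shape[0]), Bw @ target
        )
    except np.linalg.LinAlgError:
        warnings.warn("bias basis ill-conditioned; reducing order")
        return estimate_bias(vol, posteriors, model, order - 1, brain_mask)
    log_b = basis.T @ coeff.astype(np.float32)
    log_b -= log_b[brain].mean()
    np.clip(log_b, -1.5, 1.5, out=log_b)
    return BiasField(
        coefficients=np.asarray(coeff, float),
        order=order,
        field=Volume3D(
            np.exp(log_b).reshape(shape).astype(np.float32),
            vol.affine.copy(),
            "bias field",
        ),
    )


class ConstrainedGaussianMixture:
    """Model object for the constrained prior-weighted mixture fit.

    Parameters
    ----------
    volume : Volume3D
        T2*-weighted intensity volume on the working grid.
    priors : TissuePriorSet
        Six-class spatial priors on the same grid.
    config : EMConfig, optional
    """

    def __init__(
        self,
        volume: Volume3D,
        priors: TissuePriorSet,
        config: EMConfig | None = None,
    ):
        self.volume = volume
        self.priors = priors
        self.config = config or EMConfig()

    def fit(
        self, init_model: MixtureModel | None = None
    ) -> "SegmentationResults":
        model, post, bias = fit_constrained_mixture(
            self.volume, self.priors, self.config, init_model=init_model
        )
        return SegmentationResults(self, model, post, bias)


class SegmentationResults:
    """Results of one constrained mixture fit."""

    def __init__(self, model_obj, mixture, posteriors, bias_field):
        self.model = model_obj
        self.mixture: MixtureModel = mixture
        self.posteriors: PosteriorMaps = posteriors
        self.bias_field: BiasField = bias_field

    @property
    def loglik(self) -> float:
        return self.mixture.loglik_trace[-1]

    @property
    def converged(self) -> bool:
        return self.mixture.converged

    def summary(self) -> str:
        mix = self.mixture
        lines = [
            "Constrained Gaussian mixture segmentation",
            "=" * 57,
            f"{'class':<8}{'comp':>5}{'weight':>10}{'mean':>12}{'std':>12}",
            "-" * 57,
        ]
        for name in mix.class_names:
            for j in range(int(mix.n_gaussians[name])):
                lines.append(
                    f"{name:<8}{j:>5}"
                    f"{mix.weights[name][j]:>10.3f}"
                    f"{mix.means[name][j]:>12.2f}"
                    f"{np.sqrt(mix.variances[name][j]):>12.2f}"
                )
        lines += [
            "-" * 57,
            f"GWM mean: {mix.mean_gwm():.2f}   "
            f"CMB bound (0.5*GWM): {0.5 * mix.mean_gwm():.2f}",
            f"log-likelihood: {self.loglik:.1f}  "
            f"iterations: {len(mix.loglik_trace)}  "
            f"converged: {mix.converged}",
        ]
        if mix.collapsed_classes:
            lines.append(f"collapsed classes: {mix.collapsed_classes}")
        return "\n".join(lines)
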