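"""Damped-sinusoid decomposition of FIDs with back-calculation to t = 0.

A (segment) FID is modelled as a sum of exponentially damped sinusoids

    s(t_n) ~ sum_k c_k exp((i 2 pi f_k - lam_k) t_n),

estimated in two stages:

1. **Hankel-SVD / matrix-pencil initialization.** A Hankel matrix built from
   the samples is rank-truncated by SVD; the shift invariance of the signal
   subspace yields the signal poles z_k = exp((i 2 pi f_k - lam_k) dt).
2. **Variable-projection refinement** (optional): nonlinear least squares
   over (f_k, lam_k) with the linear amplitudes c_k solved by projection at
   every step.

Amplitudes are always solved on the *absolute* time axis (including
``t_start``), so the returned c_k are the amplitudes at the true excitation
origin even when initial points of the FID were discarded — fitting on
absolute times avoids the noise amplification of explicitly extrapolating
stored points by exp(lam * t_start). A warning is emitted when
``lam * t_start > 3`` (back-calculated amplitude poorly constrained).

No apodization, Fourier transform, phase correction or baseline correction
is applied anywhere; phases are reported as fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.linalg import hankel
from scipy.optimize import least_squares

from .nmr_domain import FIDRecord, LorentzianComponent, time_axis

__all__ = [
    "FitOptions",
    "FitResult",
    "hankel_poles",
    "select_order",
    "amplitudes_at_origin",
    "refine",
    "fit_segment",
]

log = logging.getLogger(__name__)

#: floor for clamped non-positive decay rates (growing poles = overfitting)
_DECAY_FLOOR = 0.01
#: condition-number cap for the amplitude basis
_MAX_CONDITION = 1e12
#: lam * t_start above which back-calculation is flagged as poorly constrained
_BACKCALC_WARN = 3.0


@dataclass(frozen=True)
class FitOptions:
    """Tuning knobs of the damped-sinusoid fit.

    ``sv_threshold`` sets the model order: the count of singular values at or
    above this fraction of the largest one (capped at ``max_order``; ties on
    a plateau resolve to the smaller order for parsimony). Components are
    pruned when their amplitude falls below ``min_amplitude_fraction`` of the
    largest in-segment amplitude, or when their modelled contribution to the
    observed samples is below ``prune_snr`` times the residual RMS (removes
    noise-born components; a noiseless fit has residual ~ 0 and prunes
    nothing by this rule). ``n_hankel``/``hankel_rows`` bound the data window
    and row count of the SVD stage, which controls its cost; amplitudes are
    always solved on the full record.
    """

    max_order: int = 12
    sv_threshold: float = 0.01
    refine: bool = True
    max_iter: int = 40
    tol: float = 1e-10
    min_amplitude_fraction: float = 0.005
    prune_snr: float = 1.0
    n_hankel: int = 1024
    hankel_rows: int = 256

    def __post_init__(self) -> None:
        if not 0 < self.sv_threshold < 1:
            raise ValueError("sv_threshold must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")


@dataclass
class FitResult:
    """Fitted components (amplitudes at t = 0) plus fit diagnostics."""

    components: list[LorentzianComponent]
    residual_rms: float
    order_used: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")
        if self.order_used != len(self.components):
            raise ValueError("order_used must equal len(components)")

    @property
    def total_amplitude(self) -> float:
        return float(sum(c.amplitude for c in self.components))


def _hankel_svd(x: np.ndarray, n_use: int, rows: int):
    """Singular values and left singular vectors of the data Hankel matrix.

    Computed from the L x L Gram matrix H H^H (eigh), which is much cheaper
    than a full SVD of the L x M Hankel matrix and accurate for every
    singular value above ~sqrt(eps) of the largest — far below the
    order-selection threshold.
    """
    n = min(len(x), n_use)
    x = x[:n]
    L = min(n // 2, rows)
    if L < 2:
        raise ValueError("too few samples for Hankel analysis")
    H = hankel(x[:L], x[L - 1:n])
    gram = H @ H.conj().T
    eigvals, eigvecs = scipy.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    s = np.sqrt(np.clip(eigvals[order], 0.0, None))
    return s, eigvecs[:, order]


def _poles_from_subspace(U: np.ndarray, order: int, dt: float):
    """Signal poles from shift invariance of the rank-``order`` subspace."""
    Uk = U[:, :order]
    A, *_ = np.linalg.lstsq(Uk[:-1], Uk[1:], rcond=None)
    z = np.linalg.eigvals(A)
    freqs = np.angle(z) / (2 * np.pi * dt)
    decays = -np.log(np.abs(z)) / dt
    clamped = decays <= 0
    decays = np.where(clamped, _DECAY_FLOOR, decays)
    return freqs, decays, clamped


def hankel_poles(
    fid: FIDRecord, max_order: int, opts: FitOptions | None = None
) -> list[tuple[float, float]]:
    """Estimate (frequency Hz, decay s**-1) pairs by Hankel-SVD.

    Non-positive decays (growing signals, a symptom of overfitting) are
    clamped to a small positive floor and logged.
    """
    opts = opts or FitOptions()
    x = fid.samples
    if not np.any(x):
        raise ValueError("degenerate all-zero input")
    if len(x) < 4 * max_order:
        raise ValueError(f"need >= {4 * max_order} samples for order {max_order}")
    _, U = _hankel_svd(x, opts.n_hankel, opts.hankel_rows)
    freqs, decays, clamped = _poles_from_subspace(
        U, min(max_order, U.shape[1]), fid.params.dwell_time
    )
    if clamped.any():
        log.warning("%d growing pole(s) clamped to decay=%.2g s^-1",
                    int(clamped.sum()), _DECAY_FLOOR)
    return list(zip(freqs.tolist(), decays.tolist()))


def select_order(singular_values: np.ndarray, opts: FitOptions) -> int:
    """Model order = count of singular values >= threshold x largest.

    Capped at ``opts.max_order``; the input must be sorted descending.
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0:
        raise ValueError("empty singular value list")
    order = int(np.count_nonzero(s >= opts.sv_threshold * s[0]))
    return max(1, min(order, opts.max_order))


def _basis(t: np.ndarray, freqs: np.ndarray, decays: np.ndarray) -> np.ndarray:
    return np.exp(np.outer(t, 2j * np.pi * freqs - decays))


def amplitudes_at_origin(
    fid: FIDRecord, poles: list[tuple[float, float]]
) -> np.ndarray:
    """Solve the complex amplitudes at the true excitation origin t = 0.

    Least squares on the absolute time axis (including ``t_start``), so the
    returned coefficients are already back-calculated to t = 0.
    """
    freqs = np.array([f for f, _ in poles])
    decays = np.array([d for _, d in poles])
    t = time_axis(fid)
    B = _basis(t, freqs, decays)
    sv = scipy.linalg.svdvals(B)
    if sv[-1] == 0 or sv[0] / sv[-1] > _MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"amplitude basis condition number exceeds {_MAX_CONDITION:.0e}; "
            "lower the model order"
        )
    if fid.t_start > 0:
        worst = float(np.max(decays) * fid.t_start)
        if worst > _BACKCALC_WARN:
            log.warning(
                "back-calculation spans lam*t_start=%.1f decay constants; "
                "that amplitude is poorly constrained", worst
            )
    c, *_ = np.linalg.lstsq(B, fid.samples, rcond=None)
    return c


def _components_from(c: np.ndarray, freqs: np.ndarray,
                     decays: np.ndarray) -> list[LorentzianComponent]:
    return [
        LorentzianComponent(
            amplitude=float(abs(ck)), phase=float(np.angle(ck)),
            frequency=float(f), decay=float(d),
        )
        for ck, f, d in zip(c, freqs, decays)
    ]


def _residual_rms(fid: FIDRecord, c, freqs, decays) -> float:
    t = time_axis(fid)
    r = fid.samples - _basis(t, np.asarray(freqs), np.asarray(decays)) @ c
    return float(np.sqrt(np.mean(np.abs(r) ** 2)))


def refine(fid: FIDRecord, initial: FitResult, opts: FitOptions) -> FitResult:
    """Variable-projection refinement of frequencies and decays.

    Nonlinear least squares over (f_k, log lam_k); at every step the linear
    amplitudes are re-solved by projection. The returned residual is never
    worse than the initial one — if the optimizer fails to improve, the
    initial result is returned with ``converged=False``.
    """
    if not initial.components:
        raise ValueError("refine requires at least one component")
    t = time_axis(fid)
    y = fid.samples
    K = len(initial.components)
    f0 = np.array([c.frequency for c in initial.components])
    d0 = np.array([c.decay for c in initial.components])

    def _solve(theta: np.ndarray):
        freqs = theta[:K]
        decays = np.exp(theta[K:])
        B = _basis(t, freqs, decays)
        c, *_ = np.linalg.lstsq(B, y, rcond=None)
        return B, c, y - B @ c

    def residual(theta: np.ndarray) -> np.ndarray:
        _, _, r = _solve(theta)
        return np.concatenate([r.real, r.imag])

    def jacobian(theta: np.ndarray) -> np.ndarray:
        # analytic variable-projection Jacobian (Golub-Pereyra): with
        # P = B B^+ and r = (I - P) y,
        #   dr/dtheta_j = -[(I-P) dB_j c + (B^+)^H dB_j^H r]
        # where dB_j touches only the column of component k(j).
        B, c, r = _solve(theta)
        decays = np.exp(theta[K:])
        Bp = np.linalg.pinv(B)
        cols = np.empty((len(t), 2 * K), dtype=np.complex128)
        for k in range(K):
            for j, m in ((k, 2j * np.pi * t), (K + k, -decays[k] * t)):
                d = m * B[:, k]
                dc = d * c[k]
                term1 = dc - B @ (Bp @ dc)
                term2 = Bp.conj().T[:, k] * (d.conj() @ r)
                cols[:, j] = -(term1 + term2)
        return np.concatenate([cols.real, cols.imag])

    theta0 = np.concatenate([f0, np.log(d0)])
    sol = least_squares(
        residual, theta0, jac=jacobian, method="trf",
        xtol=opts.tol, ftol=opts.tol, gtol=opts.tol,
        max_nfev=opts.max_iter * (2 * K + 1),
    )
    freqs = sol.x[:K]
    decays = np.exp(sol.x[K:])
    try:
        c = amplitudes_at_origin(fid, list(zip(freqs, decays)))
    except np.linalg.LinAlgError:
        return FitResult(initial.components, initial.residual_rms,
                         initial.order_used, converged=False,
                         diagnostics={**initial.diagnostics, "refine": "ill-conditioned"})
    rms = _residual_rms(fid, c, freqs, decays)
    if rms > initial.residual_rms * (1 + 1e-12):
        return FitResult(initial.components, initial.residual_rms,
                         initial.order_used, converged=False,
                         diagnostics={**initial.diagnostics, "refine": "diverged"})
    diags = dict(initial.diagnostics)
    diags["refine"] = {"nfev": int(sol.nfev), "cost": float(sol.cost),
                       "status": int(sol.status)}
    return FitResult(_components_from(c, freqs, decays), rms,
                     len(freqs), converged=bool(sol.status > 0),
                     diagnostics=diags)


def fit_segment(seg: FIDRecord, opts: FitOptions | None = None) -> FitResult:
    """Full decomposition pipeline for one (segment) FID.

    select_order -> Hankel-SVD poles -> amplitudes at origin -> optional
    variable-projection refinement -> pruning. Pruned components are recorded
    in ``diagnostics['pruned']``, never silently lost; surviving amplitudes
    are re-solved after pruning. All reported amplitudes are t = 0 values.
    """
    opts = opts or FitOptions()
    if not np.any(seg.samples):
        raise ValueError("degenerate all-zero input")
    # normalize to unit RMS so the fit is scale-equivariant by construction
    # (fit(c*x) == c*fit(x) down to rounding; ratios of amplitudes cancel)
    scale = float(np.sqrt(np.mean(np.abs(seg.samples) ** 2)))
    seg = FIDRecord(
        seg.samples / scale, seg.params, t_start=seg.t_start,
        sample_id=seg.sample_id, provenance=seg.provenance,
        metadata=dict(seg.metadata),
    )
    x = seg.samples
    s, U = _hankel_svd(x, opts.n_hankel, opts.hankel_rows)
    order = select_order(s, opts)
    freqs, decays, clamped = _poles_from_subspace(U, order, seg.params.dwell_time)
    c = amplitudes_at_origin(seg, list(zip(freqs, decays)))
    rms = _residual_rms(seg, c, freqs, decays)
    result = FitResult(
        _components_from(c, freqs, decays), rms, order, converged=True,
        diagnostics={
            "singular_values": s[: opts.max_order + 2].tolist(),
            "clamped_poles": int(clamped.sum()),
        },
    )
    if opts.refine:
        result = refine(seg, result, opts)

    # prune: relative-amplitude floor and contribution-vs-residual rule
    comps = result.components
    t = time_axis(seg)
    amax = max(c_.amplitude for c_ in comps)
    keep, pruned = [], []
    for comp in comps:
        contribution = comp.amplitude * float(
            np.sqrt(np.mean(np.exp(-2 * comp.decay * t)))
        )
        if comp.amplitude < opts.min_amplitude_fraction * amax:
            pruned.append((comp, "below amplitude floor"))
        elif contribution < opts.prune_snr * result.residual_rms:
            pruned.append((comp, "below noise level"))
        else:
            keep.append(comp)
    if pruned and keep:
        poles = [(c_.frequency, c_.decay) for c_ in keep]
        c2 = amplitudes_at_origin(seg, poles)
        freqs2 = np.array([p[0] for p in poles])
        decays2 = np.array([p[1] for p in poles])
        rms2 = _residual_rms(seg, c2, freqs2, decays2)
        result = FitResult(_components_from(c2, freqs2, decays2), rms2,
                           len(keep), result.converged, result.diagnostics)
    elif pruned:
        result = FitResult([], result.residual_rms, 0, result.converged,
                           result.diagnostics)
    result.diagnostics["pruned"] = [
        {"frequency": comp.frequency, "decay": comp.decay,
         "amplitude": comp.amplitude * scale, "reason": reason}
        for comp, reason in pruned
    ]
    # undo the RMS normalization
    result.components = [
        LorentzianComponent(c_.amplitude * scale, c_.phase, c_.frequency,
                            c_.decay)
        for c_ in result.components
    ]
    result.residual_rms *= scale
    result.diagnostics["singular_values"] = [
        v * scale for v in result.diagnostics["singular_values"]
    ]
    return result
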