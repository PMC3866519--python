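"""Batched trial-loop engine.

Parameter-space partitioning needs on the order of 10^4-10^5 independent
training runs (grid points x initializations), so the per-trial loop is
implemented twice with identical semantics:

* a numba kernel (``backend="numba"``), the default when numba imports,
  which runs each simulation as a tight scalar loop; and
* a pure-numpy fallback (``backend="numpy"``) vectorized across runs.

Both follow the same per-trial schedule as the readable single-run loop
in :mod:`covisim.simulator` (which is cross-checked against them in the
test suite):

1. sensory activation I, striatal activations S_A/S_B;
2. explicit and procedural suggestions with confidences;
3. controller selection (soft switch) or explicit control (hard);
4. bootstrap injection into the explicit unit if enabled and the
   explicit system controls;
5. emitted response, feedback, reward routing;
6. RPE and dopamine from the current predicted reward;
7. three-factor weight update on the column of the striatal unit that is
   maximal after injection;
8. predicted-reward and trust updates.

Training is followed by a frozen-weight test pass over every stimulus
once, giving the asymptotic procedural-system accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly by backend selection
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

__all__ = ["BatchResult", "run_many", "HAVE_NUMBA"]


@dataclass
class BatchResult:
    """Per-run summaries from a batch of simulations."""

    test_accuracy: np.ndarray  # (R,)
    train_accuracy: np.ndarray  # (R,)
    proc_control_prop: np.ndarray  # (R,) proportion of procedural-controlled trials
    final_weights: np.ndarray | None = None  # (R, 625, 2) if requested


def _kernel_py(i_all, true_lab, exp_lab_all, h_e_all, orderings, w,
               alpha, beta, gamma, alpha_pr, d_oc, d_oe,
               fb_independent, soft, bootstrap,
               theta_e0, d_base, th_nmda, th_ampa, w_max,
               degrade_draws, use_degrade, degrade_acc,
               out_test, out_train, out_proc):
    """Reference scalar implementation; numba-compiled when available.

    ``w`` has layout (R, 2, K) so each striatal unit's column is
    contiguous, and is mutated in place.
    """
    n_runs, n_trials = orderings.shape
    n_stim, n_units = i_all.shape
    for r in range(n_runs):
        p_pred = 0.0
        theta_e = theta_e0
        n_correct = 0
        n_proc = 0
        for t in range(n_trials):
            s = orderings[r, t]
            s_a = 0.0
            s_b = 0.0
            for k in range(n_units):
                ik = i_all[s, k]
                s_a += w[r, 0, k] * ik
                s_b += w[r, 1, k] * ik
            if use_degrade:
                if degrade_draws[r, t] < degrade_acc:
                    e_lab = true_lab[s]
                else:
                    e_lab = 1 - true_lab[s]
            else:
                e_lab = exp_lab_all[s]
            h_e = h_e_all[s]
            p_lab = 0 if s_a > s_b else 1
            h_p = s_a - s_b
            if h_p < 0.0:
                h_p = -h_p
            if soft:
                expl_ctrl = theta_e * h_e >= (1.0 - theta_e) * h_p
            else:
                expl_ctrl = True
            if bootstrap and expl_ctrl:
                if e_lab == 0:
                    s_a += h_e
                else:
                    s_b += h_e
            resp = 0 if s_a > s_b else 1
            emitted = e_lab if expl_ctrl else p_lab
            correct = emitted == true_lab[s]
            if fb_independent:
                rewarded = p_lab == true_lab[s]
            else:
                rewarded = correct
            r_n = 1.0 if rewarded else -1.0
            err = r_n - p_pred
            if err > 1.0:
                dop = 1.0
            elif err < -0.25:
                dop = 0.0
            else:
                dop = 0.8 * err + 0.2
            s_j = s_a if resp == 0 else s_b
            nmda = s_j - th_nmda
            if nmda > 0.0:
                gain = dop - d_base
                if gain > 0.0:
                    a_r = alpha[r] * nmda * gain
                    for k in range(n_units):
                        wk = w[r, resp, k]
                        wk += a_r * i_all[s, k] * (w_max - wk)
                        if wk > w_max:
                            wk = w_max
                        elif wk < 0.0:
                            wk = 0.0
                        w[r, resp, k] = wk
                elif gain < 0.0:
                    b_r = beta[r] * nmda * (-gain)
                    for k in range(n_units):
                        wk = w[r, resp, k]
                        wk -= b_r * i_all[s, k] * wk
                        if wk > w_max:
                            wk = w_max
                        elif wk < 0.0:
                            wk = 0.0
                        w[r, resp, k] = wk
            else:
                band = (-nmda) * (s_j - th_ampa)
                if band > 0.0 and gamma[r] > 0.0:
                    g_r = gamma[r] * band
                    for k in range(n_units):
                        wk = w[r, resp, k]
                        wk -= g_r * i_all[s, k] * wk
                        if wk > w_max:
                            wk = w_max
                        elif wk < 0.0:
                            wk = 0.0
                        w[r, resp, k] = wk
            p_pred += alpha_pr[r] * (r_n - p_pred)
            if e_lab == true_lab[s]:
                theta_e += d_oc[r] * (1.0 - theta_e)
            else:
                theta_e -= d_oe[r] * theta_e
            if correct:
                n_correct += 1
            if not expl_ctrl:
                n_proc += 1
        out_train[r] = n_correct / n_trials
        out_proc[r] = n_proc / n_trials
        n_test = 0
        for s in range(n_stim):
            s_a = 0.0
            s_b = 0.0
            for k in range(n_units):
                ik = i_all[s, k]
                s_a += w[r, 0, k] * ik
                s_b += w[r, 1, k] * ik
            pred = 0 if s_a > s_b else 1
            if pred == true_lab[s]:
                n_test += 1
        out_test[r] = n_test / n_stim


if HAVE_NUMBA:
    _kernel_numba = numba.njit(cache=True, fastmath=False)(_kernel_py)


def _run_numpy(i_all, true_lab, exp_lab_all, h_e_all, orderings, w,
               alpha, beta, gamma, alpha_pr, d_oc, d_oe,
               fb_independent, soft, bootstrap,
               theta_e0, d_base, th_nmda, th_ampa, w_max,
               degrade_draws, use_degrade, degrade_acc,
               out_test, out_train, out_proc):
    """Numpy fallback vectorized across runs."""
    n_runs, n_trials = orderings.shape
    idx = np.arange(n_runs)
    p_pred = np.zeros(n_runs)
    theta_e = np.full(n_runs, theta_e0)
    n_correct = np.zeros(n_runs, dtype=np.int64)
    n_proc = np.zeros(n_runs, dtype=np.int64)
    for t in range(n_trials):
        s = orderings[:, t]
        i_t = i_all[s]  # (R, K)
        s_ab = np.einsum("rjk,rk->rj", w, i_t)  # (R, 2)
        truth = true_lab[s]
        if use_degrade:
            e_lab = np.where(degrade_draws[:, t] < degrade_acc, truth, 1 - truth)
        else:
            e_lab = exp_lab_all[s]
        h_e = h_e_all[s]
        p_lab = (s_ab[:, 0] <= s_ab[:, 1]).astype(np.int64)
        h_p = np.abs(s_ab[:, 0] - s_ab[:, 1])
        if soft:
            expl_ctrl = theta_e * h_e >= (1.0 - theta_e) * h_p
        else:
            expl_ctrl = np.ones(n_runs, dtype=bool)
        if bootstrap:
            inj = np.where(expl_ctrl, h_e, 0.0)
            s_ab[idx, e_lab] += inj
        resp = (s_ab[:, 0] <= s_ab[:, 1]).astype(np.int64)
        emitted = np.where(expl_ctrl, e_lab, p_lab)
        correct = emitted == truth
        rewarded = (p_lab == truth) if fb_independent else correct
        r_n = np.where(rewarded, 1.0, -1.0)
        err = r_n - p_pred
        dop = np.where(err > 1.0, 1.0,
                       np.where(err < -0.25, 0.0, 0.8 * err + 0.2))
        s_j = s_ab[idx, resp]
        nmda = np.maximum(s_j - th_nmda, 0.0)
        band = np.maximum(th_nmda - s_j, 0.0) * np.maximum(s_j - th_ampa, 0.0)
        w_col = w[idx, resp, :]  # (R, K) gathered copy
        dw = (alpha * nmda * np.maximum(dop - d_base, 0.0))[:, None] \
            * i_t * (w_max - w_col) \
            - (beta * nmda * np.maximum(d_base - dop, 0.0))[:, None] \
            * i_t * w_col \
            - (gamma * band)[:, None] * i_t * w_col
        w[idx, resp, :] = np.clip(w_col + dw, 0.0, w_max)
        p_pred += alpha_pr * (r_n - p_pred)
        e_ok = e_lab == truth
        theta_e = np.where(e_ok, theta_e + d_oc * (1.0 - theta_e),
                           theta_e - d_oe * theta_e)
        n_correct += correct
        n_proc += ~expl_ctrl
    out_train[:] = n_correct / n_trials
    out_proc[:] = n_proc / n_trials
    s_test = np.einsum("rjk,nk->rnj", w, i_all)  # (R, N, 2)
    pred = (s_test[:, :, 0] <= s_test[:, :, 1]).astype(np.int64)
    out_test[:] = (pred == true_lab[None, :]).mean(axis=1)


def run_many(i_all, true_labels, exp_labels, h_e_abs, orderings, w0,
             *, alpha, beta, gamma=0.0, alpha_pr, delta_oc=0.01,
             delta_oe=0.01, feedback_independent, soft_switch, bootstrap,
             theta_e_init=0.99, d_base=0.2, theta_nmda=0.1, theta_ampa=0.01,
             w_max=1.0, degrade_draws=None, degrade_acc=None,
             return_weights=False, backend="auto") -> BatchResult:
    """Run R independent simulations sharing one stimulus set.

    Parameters
    ----------
    i_all : (N, 625) sensory activations of every stimulus.
    true_labels, exp_labels, h_e_abs : (N,) per-stimulus category labels,
        fitted-rule explicit labels, and explicit confidences.
    orderings : (R, T) stimulus index per run and trial.
    w0 : (R, 625, 2) initial weights (copied; not mutated).
    alpha, beta, gamma, alpha_pr, delta_oc, delta_oe : scalar or (R,)
        per-run learning parameters.
    degrade_draws, degrade_acc : optional (R, T) uniforms and target
        accuracy for the degraded explicit responder (replaces
        ``exp_labels``; confidences still come from ``h_e_abs``).
    """
    i_all = np.ascontiguousarray(i_all, dtype=np.float64)
    true_labels = np.ascontiguousarray(true_labels, dtype=np.int64)
    exp_labels = np.ascontiguousarray(exp_labels, dtype=np.int64)
    h_e_abs = np.ascontiguousarray(h_e_abs, dtype=np.float64)
    orderings = np.ascontiguousarray(orderings, dtype=np.int64)
    n_runs, _ = orderings.shape
    w0 = np.asarray(w0, dtype=np.float64)
    if w0.shape != (n_runs, i_all.shape[1], 2):
        raise ValueError("w0 must have shape (n_runs, n_units, 2)")
    if orderings.size and (orderings.min() < 0
                           or orderings.max() >= i_all.shape[0]):
        raise ValueError("ordering indexes outside the stimulus set")
    w = np.ascontiguousarray(np.transpose(w0, (0, 2, 1)))  # (R, 2, K)

    def as_vec(x):
        x = np.asarray(x, dtype=np.float64)
        return np.ascontiguousarray(np.broadcast_to(x, (n_runs,)))

    use_degrade = degrade_draws is not None
    if use_degrade:
        if degrade_acc is None:
            raise ValueError("degrade_acc required with degrade_draws")
        degrade_draws = np.ascontiguousarray(degrade_draws, dtype=np.float64)
        if degrade_draws.shape != orderings.shape:
            raise ValueError("degrade_draws must match orderings shape")
    else:
        degrade_draws = np.zeros((1, 1))
        degrade_acc = 0.0

    out_test = np.empty(n_runs)
    out_train = np.empty(n_runs)
    out_proc = np.empty(n_runs)
    args = (i_all, true_labels, exp_labels, h_e_abs, orderings, w,
            as_vec(alpha), as_vec(beta), as_vec(gamma), as_vec(alpha_pr),
            as_vec(delta_oc), as_vec(delta_oe),
            bool(feedback_independent), bool(soft_switch), bool(bootstrap),
            float(theta_e_init), float(d_base), float(theta_nmda),
            float(theta_ampa), float(w_max),
            degrade_draws, use_degrade, float(degrade_acc),
            out_test, out_train, out_proc)
    if backend == "auto":
        backend = "numba" if HAVE_NUMBA else "numpy"
    if backend == "numba":
        if not HAVE_NUMBA:
            raise RuntimeError("numba backend requested but numba not available")
        _kernel_numba(*args)
    elif backend == "numpy":
        _run_numpy(*args)
    else:
        raise ValueError(f"unknown backend: {backend!r}")
    return BatchResult(
        test_accuracy=out_test,
        train_accuracy=out_train,
        proc_control_prop=out_proc,
        final_weights=np.transpose(w, (0, 2, 1)) if return_weights else None,
    )
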