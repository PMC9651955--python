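"""Numba kernel for lineage simulation.

A network is first compiled to flat arrays (see ``compile_network`` in
``simulator``); the kernel then integrates concentration dynamics
(forward-Euler / tau-leaping), exponential volume growth, the hazard-gated
control phase and the noisy timer phase, divisions, and the optional
control-volume and perturbation protocols — everything the inner loop of
an evolutionary run needs, in one jitted pass.

Encoding conventions shared with the wrapper:

- species arrays cover all dynamic species (proteins + implicit
  complexes); the switch is not a dynamic species and enters transcription
  as an exact 0/1 input, encoded as source index -1;
- ``structure`` 0 = control phase first (G1 size control, S/G2/M timer),
  1 = timer first (fission-yeast-like: G1 timer, S/G2/M control);
  the switch is 1 during the timer phase and 0 during the control phase;
- ``sensing`` 0 = quantity ([I]*V), 1 = concentration ([I]);
- ``cv_mode`` 0 = off, 1 = clamp the sensed volume at ``Vc``,
  2 = reset the actual volume to ``Vc`` at each division;
- status codes: 0 = ran to T_total, 1 = died (V < Vmin), 2 = non-finite
  state, 3 = cycle buffer full.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIED = 1
STATUS_NONFINITE = 2
STATUS_FULL = 3


@njit(cache=True)
def run_lineage_kernel(
    seed,
    # network (compiled)
    x0, delta, rho0,
    asrc, atgt, arho, aK, an,
    rsrc, rtgt, rK, rn,
    cA, cB, cC, ckon, ckoff,
    idx_I,
    # cycle configuration
    lam0, dt, t_total, V0,
    structure, sensing,
    f_T, timer_w, growth_cv, part_cv,
    noise_on, omega0,
    h_max, K_h, n_h,
    V_min, V_max,
    cv_mode, Vc,
    perturb_cycle, perturb_V,
    max_cycles, trace_stride,
):
    np.random.seed(seed)
    n = x0.shape[0]
    nact = asrc.shape[0]
    nrep = rsrc.shape[0]
    ncpx = cA.shape[0]

    tau = np.log(2.0) / lam0

    # per-cycle outputs
    t_birth = np.zeros(max_cycles)
    v_birth = np.zeros(max_cycles)
    t_g1s = np.zeros(max_cycles)
    v_g1s = np.zeros(max_cycles)
    t_div = np.zeros(max_cycles)
    v_div = np.zeros(max_cycles)
    lam_used = np.zeros(max_cycles)
    perturbed = np.zeros(max_cycles, dtype=np.int8)
    cyc_capped = np.zeros(max_cycles, dtype=np.int8)
    conc_birth = np.zeros((max_cycles, n))
    conc_g1s = np.zeros((max_cycles, n))

    n_steps = int(np.ceil(t_total / dt))
    if trace_stride > 0:
        ntr = n_steps // trace_stride + 2
        tr_t = np.zeros(ntr)
        tr_v = np.zeros(ntr)
        tr_sw = np.zeros(ntr, dtype=np.int8)
        tr_x = np.zeros((ntr, n))
    else:
        tr_t = np.zeros(0)
        tr_v = np.zeros(0)
        tr_sw = np.zeros(0, dtype=np.int8)
        tr_x = np.zeros((0, n))
    n_trace = 0

    x = x0.copy()
    prod = np.zeros(n)
    V = V0
    t = 0.0
    status = STATUS_OK
    capped = False
    cyc = 0  # current (open) cycle index

    # growth rate of the first cycle
    lam = lam0
    if growth_cv > 0.0:
        for _ in range(100):
            lam = lam0 * (1.0 + growth_cv * np.random.standard_normal())
            if lam > 0.0:
                break
        if lam <= 0.0:
            lam = lam0
    gfac = np.exp(lam * dt)

    # open cycle 0
    t_birth[0] = t
    v_birth[0] = V
    lam_used[0] = lam
    for i in range(n):
        conc_birth[0, i] = x[i]
    if perturb_cycle == 0 and perturb_V > 0.0:
        V = perturb_V
        v_birth[0] = V
        perturbed[0] = 1

    # mode: 0 = control phase, 1 = timer phase
    if structure == 0:
        mode = 0
        deadline = 0.0
    else:
        mode = 1
        deadline = t + f_T * tau * (1.0 + timer_w * (2.0 * np.random.random() - 1.0))

    step = 0
    while step < n_steps:
        step += 1
        sw = 1.0 if mode == 1 else 0.0

        # --- production rates: (rho0 + sum act) * prod rep -------------
        for i in range(n):
            prod[i] = rho0[i]
        for j in range(nact):
            s = asrc[j]
            if s == -1:
                h = sw
            else:
                c = x[s]
                cn = c ** an[j]
                h = cn / (aK[j] ** an[j] + cn)
            prod[atgt[j]] += arho[j] * h
        for j in range(nrep):
            s = rsrc[j]
            if s == -1:
                h = 1.0 - sw
            else:
                c = x[s]
                kn = rK[j] ** rn[j]
                h = kn / (kn + c ** rn[j])
            prod[rtgt[j]] *= h

        # --- tau-leap / Euler update ----------------------------------
        # conservation caps keep the explicit step from manufacturing
        # mass when a mutant's rates are stiff relative to dt
        if noise_on == 1:
            amp = 1.0 / np.sqrt(omega0 * V)
            for i in range(n):
                inc = prod[i] * dt
                if inc > 0.0:
                    inc += np.sqrt(inc) * amp * np.random.standard_normal()
                dg = delta[i] * x[i] * dt
                if dg > 0.0:
                    dg += np.sqrt(dg) * amp * np.random.standard_normal()
                if dg > x[i]:
                    dg = x[i]
                x[i] += inc - dg - lam * x[i] * dt
            for j in range(ncpx):
                on = ckon[j] * x[cA[j]] * x[cB[j]] * dt
                if on > 0.0:
                    on += np.sqrt(on) * amp * np.random.standard_normal()
                off = ckoff[j] * x[cC[j]] * dt
                if off > 0.0:
                    off += np.sqrt(off) * amp * np.random.standard_normal()
                flux = on - off
                if flux > 0.0:
                    if flux > x[cA[j]]:
                        flux = x[cA[j]]
                    if flux > x[cB[j]]:
                        flux = x[cB[j]]
                elif flux < -x[cC[j]]:
                    flux = -x[cC[j]]
                x[cA[j]] -= flux
                x[cB[j]] -= flux
                x[cC[j]] += flux
        else:
            for i in range(n):
                dg = delta[i] * x[i] * dt
                if dg > x[i]:
                    dg = x[i]
                x[i] += prod[i] * dt - dg - lam * x[i] * dt
            for j in range(ncpx):
                flux = (ckon[j] * x[cA[j]] * x[cB[j]] - ckoff[j] * x[cC[j]]) * dt
                if flux > 0.0:
                    if flux > x[cA[j]]:
                        flux = x[cA[j]]
                    if flux > x[cB[j]]:
                        flux = x[cB[j]]
                elif flux < -x[cC[j]]:
                    flux = -x[cC[j]]
                x[cA[j]] -= flux
                x[cB[j]] -= flux
                x[cC[j]] += flux
        for i in range(n):
            if x[i] < 0.0:
                x[i] = 0.0

        V *= gfac
        t = step * dt

        if not np.isfinite(V):
            status = STATUS_NONFINITE
            break
        if V > V_max:
            V = V_max
            capped = True
            cyc_capped[cyc] = 1
        if V < V_min:
            status = STATUS_DIED
            break

        if trace_stride > 0 and step % trace_stride == 0:
            tr_t[n_trace] = t
            tr_v[n_trace] = V
            tr_sw[n_trace] = 1 if mode == 1 else 0
            for i in range(n):
                tr_x[n_trace, i] = x[i]
            n_trace += 1

        divide = False
        if mode == 0:
            # hazard-gated control phase
            Vs = Vc if cv_mode == 1 else V
            sensed = x[idx_I] * Vs if sensing == 0 else x[idx_I]
            kn = K_h ** n_h
            h = h_max * kn / (kn + sensed ** n_h)
            if np.random.random() < 1.0 - np.exp(-h * dt):
                if structure == 0:
                    # G1/S transition; enter the S/G2/M timer
                    t_g1s[cyc] = t
                    v_g1s[cyc] = V
                    for i in range(n):
                        conc_g1s[cyc, i] = x[i]
                    mode = 1
                    deadline = t + f_T * tau * (
                        1.0 + timer_w * (2.0 * np.random.random() - 1.0))
                else:
                    divide = True
        else:
            if t >= deadline:
                if structure == 0:
                    divide = True
                else:
                    # end of the G1 timer = G1/S transition
                    t_g1s[cyc] = t
                    v_g1s[cyc] = V
                    for i in range(n):
                        conc_g1s[cyc, i] = x[i]
                    mode = 0

        if divide:
            ok = True
            for i in range(n):
                if not np.isfinite(x[i]):
                    ok = False
            if not ok:
                status = STATUS_NONFINITE
                break
            t_div[cyc] = t
            v_div[cyc] = V
            cyc += 1
            if cyc >= max_cycles:
                status = STATUS_FULL
                break
            # division: volume split, concentrations conserved
            if cv_mode == 2:
                V = Vc
            else:
                f = 0.5
                if part_cv > 0.0:
                    sd = 0.5 * part_cv
                    for _ in range(100):
                        f = 0.5 + sd * np.random.standard_normal()
                        if abs(f - 0.5) < 3.0 * sd and 0.0 < f < 1.0:
                            break
                V = f * V
            if cyc == perturb_cycle and perturb_V > 0.0:
                V = perturb_V
                perturbed[cyc] = 1
            if growth_cv > 0.0:
                for _ in range(100):
                    lam = lam0 * (1.0 + growth_cv * np.random.standard_normal())
                    if lam > 0.0:
                        break
                if lam <= 0.0:
                    lam = lam0
                gfac = np.exp(lam * dt)
            t_birth[cyc] = t
            v_birth[cyc] = V
            lam_used[cyc] = lam
            for i in range(n):
                conc_birth[cyc, i] = x[i]
            if structure == 0:
                mode = 0
            else:
                mode = 1
                deadline = t + f_T * tau * (
                    1.0 + timer_w * (2.0 * np.random.random() - 1.0))

    return (status, capped, cyc, t,
            t_birth, v_birth, t_g1s, v_g1s, t_div, v_div,
            lam_used, perturbed, cyc_capped, conc_birth, conc_g1s,
            n_trace, tr_t, tr_v, tr_sw, tr_x)
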