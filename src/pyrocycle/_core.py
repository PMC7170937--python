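"""Jit-compiled monthly time-stepping kernel.

The kernel is the single source of truth for the step order:

1. GPP and autotrophic respiration (Ra = f_auto * GPP; temperature enters
   through the g_T scalar inside GPP),
2. NPP allocation to the live pools and labile release to foliar,
3. natural turnover (foliar/root -> litter, wood -> SOM),
4. decomposition scaled by g_T * g_W (litter and SOM mineralization,
   litter -> SOM humification),
5. fire: combustion of all pools plus fire-induced mortality of live
   biomass to litter,
6. water-bucket update.

Whenever the fluxes demanded from a pool in a phase exceed its content,
all outfluxes of that pool are scaled by a common factor so the pool ends
at exactly zero (proportional limitation); pools therefore never go
negative and carbon is conserved by construction.

Parameter/pool/flux column orders match ``pyrocycle.types``.
"""

import numpy as np
from numba import njit

# parameter indices (PARAM_NAMES order)
_LUE, _FAUTO, _AF, _AL, _AR, _LREL, _LCMA, _TF, _TR, _TW = range(10)
_DL, _DS, _L2S, _THETA, _WHALF, _CCF, _CCW, _CCL, _CCS, _RES = range(10, 20)

NPOOL = 7
NFLUX = 9


@njit(cache=True)
def _gt(theta, t_mean, t_ref, cap):
    g = np.exp(theta * (t_mean - t_ref))
    if g > cap:
        g = cap
    return g


@njit(cache=True)
def simulate_core(theta, init, t_mean, precip, sw_rad, days, ba, consts):
    """Run the monthly model; returns (pools (T,7), fluxes (T,9)).

    consts = [k_ext, t_ref, gt_cap, w_max, wue].
    """
    k_ext = consts[0]
    t_ref = consts[1]
    gt_cap = consts[2]
    w_max = consts[3]
    wue = consts[4]

    n = t_mean.shape[0]
    pools = np.empty((n, NPOOL))
    fluxes = np.empty((n, NFLUX))

    labile = init[0]
    foliar = init[1]
    root = init[2]
    wood = init[3]
    litter = init[4]
    som = init[5]
    water = init[6]

    for i in range(n):
        g_t = _gt(theta[_THETA], t_mean[i], t_ref, gt_cap)

        # (1) GPP and autotrophic respiration
        lai = foliar / theta[_LCMA]
        apar = 0.5 * sw_rad[i] * (1.0 - np.exp(-k_ext * lai))
        gpp = theta[_LUE] * apar * g_t * days[i]
        ra = theta[_FAUTO] * gpp
        npp = gpp - ra

        # (2) allocation and labile release
        labile += theta[_AL] * npp
        foliar += theta[_AF] * npp
        root += theta[_AR] * npp
        wood += (1.0 - theta[_AF] - theta[_AL] - theta[_AR]) * npp
        rel = labile * theta[_LREL]
        if rel > labile:
            rel = labile
        labile -= rel
        foliar += rel

        # (3) natural turnover
        t_fol = foliar * theta[_TF]
        if t_fol > foliar:
            t_fol = foliar
        foliar -= t_fol
        t_root = root * theta[_TR]
        if t_root > root:
            t_root = root
        root -= t_root
        t_wood = wood * theta[_TW]
        if t_wood > wood:
            t_wood = wood
        wood -= t_wood
        litter += t_fol + t_root
        som += t_wood

        # (4) decomposition (temperature x moisture scaled)
        g_w = water / (water + theta[_WHALF])
        g = g_t * g_w
        rh_l = litter * theta[_DL] * g
        to_som = litter * theta[_L2S] * g
        out = rh_l + to_som
        if out > litter and out > 0.0:
            scale = litter / out
            rh_l *= scale
            to_som *= scale
        litter -= rh_l + to_som
        som += to_som
        rh_s = som * theta[_DS] * g
        if rh_s > som:
            rh_s = som
        som -= rh_s

        # (5) fire: combustion + fire-induced mortality of live biomass
        b = ba[i]
        fire = 0.0
        m_lab = 0.0
        m_fol = 0.0
        m_root = 0.0
        m_wood = 0.0
        if b > 0.0:
            mort_fac = (1.0 - theta[_RES])
            c_lab = labile * b * theta[_CCF]
            m_lab = labile * b * (1.0 - theta[_CCF]) * mort_fac
            c_fol = foliar * b * theta[_CCF]
            m_fol = foliar * b * (1.0 - theta[_CCF]) * mort_fac
            c_root = root * b * theta[_CCF]
            m_root = root * b * (1.0 - theta[_CCF]) * mort_fac
            c_wood = wood * b * theta[_CCW]
            m_wood = wood * b * (1.0 - theta[_CCW]) * mort_fac
            c_lit = litter * b * theta[_CCL]
            c_som = som * b * theta[_CCS]
            fire = c_lab + c_fol + c_root + c_wood + c_lit + c_som
            labile -= c_lab + m_lab
            foliar -= c_fol + m_fol
            root -= c_root + m_root
            wood -= c_wood + m_wood
            litter += m_lab + m_fol + m_root + m_wood - c_lit
            som -= c_som

        # (6) water bucket
        et = gpp / wue
        water = water + precip[i] - et
        if water < 0.0:
            water = 0.0
        elif water > w_max:
            water = w_max

        pools[i, 0] = labile
        pools[i, 1] = foliar
        pools[i, 2] = root
        pools[i, 3] = wood
        pools[i, 4] = litter
        pools[i, 5] = som
        pools[i, 6] = water
        fluxes[i, 0] = gpp
        fluxes[i, 1] = ra
        fluxes[i, 2] = rh_l
        fluxes[i, 3] = rh_s
        fluxes[i, 4] = fire
        fluxes[i, 5] = m_lab
        fluxes[i, 6] = m_fol
        fluxes[i, 7] = m_root
        fluxes[i, 8] = m_wood

    return pools, fluxes
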