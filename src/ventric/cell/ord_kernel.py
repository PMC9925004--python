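"""Numba kernel for the O'Hara–Rudy human ventricular myocyte model.

The model is evaluated simultaneously for an array of "nodes" (myocytes),
each with its own parameter-multiplier column, so the same kernel drives
single-cell pacing and the reaction half-step of the tissue solver.

State layout (rows of the ``(NS, n)`` state array) follows the original
published ordering: membrane potential, intracellular/subspace Na+, K+ and
Ca2+ concentrations, SR calcium, the Hodgkin–Huxley-style gates of INa,
INaL, Ito, ICaL, IKr, IKs and IK1, the two ryanodine-release fluxes and
the CaMKII trap fraction.

Integration: Rush–Larsen exponential update for every gate with a
voltage-only time constant, forward Euler for concentrations, fluxes and
the membrane potential.  Units: ms, mV, mmol/L, uA/uF.
"""

import numpy as np
from numba import njit

NS = 41  # number of state variables

# state indices
IV = 0
INAI, INASS, IKI, IKSS, ICAI, ICASS, ICANSR, ICAJSR = 1, 2, 3, 4, 5, 6, 7, 8
IM, IHF, IHS, IJ, IHSP, IJP = 9, 10, 11, 12, 13, 14
IML, IHL, IHLP = 15, 16, 17
IA, IIF, IIS, IAP, IIFP, IISP = 18, 19, 20, 21, 22, 23
ID, IFF, IFS, IFCAF, IFCAS, IJCA, INCA, IFFP, IFCAFP = 24, 25, 26, 27, 28, 29, 30, 31, 32
IXRF, IXRS, IXS1, IXS2, IXK1 = 33, 34, 35, 36, 37
IJRELNP, IJRELP, ICAMKT = 38, 39, 40

# parameter-multiplier rows (per node); all default to 1 except epi flag
NP = 14
PGNA, PGNAL, PGTO, PPCA, PGKR, PGKS, PGK1, PGNCX, PPNAK, PGKB, PJUP, PJREL, PCMDN, PEPI = range(NP)

# physical constants
_R = 8314.0
_T = 310.0
_F = 96485.0
_RTF = _R * _T / _F

# cell geometry (cm)
_L = 0.01
_RAD = 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL

# extracellular concentrations (mmol/L)
_NAO = 140.0
_CAO = 1.8
_KO = 5.4


def initial_state(n: int) -> np.ndarray:
    """Published resting initial conditions, tiled for ``n`` nodes.

    These correspond to the endocardial variant paced to steady state at a
    1000-ms cycle; they sit close enough to the resting equilibrium of all
    variants to serve as the universal starting point before pacing.
    """
    y = np.zeros(NS)
    y[IV] = -87.84
    y[INAI] = 7.23
    y[INASS] = 7.23
    y[IKI] = 143.79
    y[IKSS] = 143.79
    y[ICAI] = 8.54e-5
    y[ICASS] = 8.43e-5
    y[ICANSR] = 1.61
    y[ICAJSR] = 1.56
    y[IM] = 0.0074621
    y[IHF] = 0.692591
    y[IHS] = 0.692574
    y[IJ] = 0.692477
    y[IHSP] = 0.448501
    y[IJP] = 0.692413
    y[IML] = 0.000194015
    y[IHL] = 0.496116
    y[IHLP] = 0.265885
    y[IA] = 0.00101185
    y[IIF] = 0.999542
    y[IIS] = 0.589579
    y[IAP] = 0.000515567
    y[IIFP] = 0.999542
    y[IISP] = 0.641861
    y[ID] = 2.43e-9
    y[IFF] = 1.0
    y[IFS] = 0.910671
    y[IFCAF] = 1.0
    y[IFCAS] = 0.99982
    y[IJCA] = 0.999977
    y[INCA] = 0.00267171
    y[IFFP] = 1.0
    y[IFCAFP] = 1.0
    y[IXRF] = 8.26608e-6
    y[IXRS] = 0.453268
    y[IXS1] = 0.270492
    y[IXS2] = 0.0001963
    y[IXK1] = 0.996801
    y[IJRELNP] = 2.53943e-5
    y[IJRELP] = 3.17262e-7
    y[ICAMKT] = 0.0124065
    return np.repeat(y[:, None], n, axis=1)


@njit(cache=True, fastmath=True)
def step(S, P, istim, excitable, dt):  # noqa: C901  (single flat kernel by design)
    """Advance every node one reaction step of ``dt`` ms in place.

    ``S``: (NS, n) states; ``P``: (NP, n) parameter multipliers;
    ``istim``: (n,) stimulus current in uA/uF (depolarizing negative, the
    sign convention of the source model); ``excitable``: (n,) uint8 mask —
    non-excitable nodes are skipped entirely (passive tissue).
    """
    n = S.shape[1]
    for k in range(n):
        if excitable[k] == 0:
            continue
        v = S[IV, k]
        nai = S[INAI, k]
        nass = S[INASS, k]
        ki = S[IKI, k]
        kss = S[IKSS, k]
        cai = S[ICAI, k]
        cass = S[ICASS, k]
        cansr = S[ICANSR, k]
        cajsr = S[ICAJSR, k]

        epi = P[PEPI, k] > 0.5

        vfrt = v / _RTF
        vffrt = v * _F / _RTF

        # --- CaMK ---
        KmCaMK = 0.15
        CaMKb = 0.05 * (1.0 - S[ICAMKT, k]) / (1.0 + 0.0015 / cass)
        CaMKa = CaMKb + S[ICAMKT, k]
        dCaMKt = 0.05 * CaMKb * (CaMKb + S[ICAMKT, k]) - 0.00068 * S[ICAMKT, k]

        # --- reversal potentials ---
        ENa = _RTF * np.log(_NAO / nai)
        EK = _RTF * np.log(_KO / ki)
        PKNa = 0.01833
        EKs = _RTF * np.log((_KO + PKNa * _NAO) / (ki + PKNa * nai))

        # --- INa (fast) ---
        mss = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
        tm = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77) + 8.552 * np.exp(-(v + 77.42) / 5.955))
        hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
        thf = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285) + 6.149 * np.exp((v + 0.5096) / 20.27))
        ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05) + 0.3343 * np.exp((v + 5.730) / 56.66))
        jss = hss
        tj = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281) + 0.3052 * np.exp((v + 0.9941) / 38.45))
        hssp = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
        thsp = 3.0 * ths
        tjp = 1.46 * tj

        S[IM, k] = mss + (S[IM, k] - mss) * np.exp(-dt / tm)
        S[IHF, k] = hss + (S[IHF, k] - hss) * np.exp(-dt / thf)
        S[IHS, k] = hss + (S[IHS, k] - hss) * np.exp(-dt / ths)
        S[IJ, k] = jss + (S[IJ, k] - jss) * np.exp(-dt / tj)
        S[IHSP, k] = hssp + (S[IHSP, k] - hssp) * np.exp(-dt / thsp)
        S[IJP, k] = jss + (S[IJP, k] - jss) * np.exp(-dt / tjp)

        h = 0.99 * S[IHF, k] + 0.01 * S[IHS, k]
        hp = 0.99 * S[IHF, k] + 0.01 * S[IHSP, k]
        fINap = 1.0 / (1.0 + KmCaMK / CaMKa)
        GNa = 75.0 * P[PGNA, k]
        m3 = S[IM, k] * S[IM, k] * S[IM, k]
        INa = GNa * (v - ENa) * m3 * ((1.0 - fINap) * h * S[IJ, k] + fINap * hp * S[IJP, k])

        # --- INaL ---
        mLss = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
        tmL = tm
        hLss = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
        thL = 200.0
        hLssp = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
        thLp = 3.0 * thL
        S[IML, k] = mLss + (S[IML, k] - mLss) * np.exp(-dt / tmL)
        S[IHL, k] = hLss + (S[IHL, k] - hLss) * np.exp(-dt / thL)
        S[IHLP, k] = hLssp + (S[IHLP, k] - hLssp) * np.exp(-dt / thLp)
        GNaL = 0.0075 * P[PGNAL, k]
        if epi:
            GNaL *= 0.6
        fINaLp = fINap
        INaL = GNaL * (v - ENa) * S[IML, k] * ((1.0 - fINaLp) * S[IHL, k] + fINaLp * S[IHLP, k])

        # --- Ito ---
        ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
        ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.41) / 29.38)))
                       + 3.5 / (1.0 + np.exp((v + 100.0) / 29.38)))
        iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
        if epi:
            delta_epi = 1.0 - 0.95 / (1.0 + np.exp((v + 70.0) / 5.0))
        else:
            delta_epi = 1.0
        tiF = 4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0) + 0.08004 * np.exp((v + 50.0) / 16.59))
        tiS = 23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05) + 1.780e-8 * np.exp((v + 114.1) / 8.079))
        tiF *= delta_epi
        tiS *= delta_epi
        AiF = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
        AiS = 1.0 - AiF
        assp = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
        dti_develop = 1.354 + 1.0e-4 / (np.exp((v - 167.4) / 15.89) + np.exp(-(v - 12.23) / 0.2154))
        dti_recover = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
        tiFp = dti_develop * dti_recover * tiF
        tiSp = dti_develop * dti_recover * tiS

        S[IA, k] = ass + (S[IA, k] - ass) * np.exp(-dt / ta)
        S[IIF, k] = iss + (S[IIF, k] - iss) * np.exp(-dt / tiF)
        S[IIS, k] = iss + (S[IIS, k] - iss) * np.exp(-dt / tiS)
        S[IAP, k] = assp + (S[IAP, k] - assp) * np.exp(-dt / ta)
        S[IIFP, k] = iss + (S[IIFP, k] - iss) * np.exp(-dt / tiFp)
        S[IISP, k] = iss + (S[IISP, k] - iss) * np.exp(-dt / tiSp)

        i_gate = AiF * S[IIF, k] + AiS * S[IIS, k]
        ip_gate = AiF * S[IIFP, k] + AiS * S[IISP, k]
        Gto = 0.02 * P[PGTO, k]
        if epi:
            Gto *= 4.0
        fItop = fINap
        Ito = Gto * (v - EK) * ((1.0 - fItop) * S[IA, k] * i_gate + fItop * S[IAP, k] * ip_gate)

        # --- ICaL / ICaNa / ICaK ---
        dss = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
        td = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
        fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
        tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0) + 0.0045 * np.exp((v + 20.0) / 10.0))
        tfs = 1000.0 + 1.0 / (3.5e-5 * np.exp(-(v + 5.0) / 4.0) + 3.5e-5 * np.exp((v + 5.0) / 6.0))
        fcass = fss
        tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0) + 0.04 * np.exp((v - 4.0) / 7.0))
        tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0) + 0.00012 * np.exp(v / 7.0))
        Afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
        Afcas = 1.0 - Afcaf
        tjca = 75.0
        tffp = 2.5 * tff
        tfcafp = 2.5 * tfcaf

        S[ID, k] = dss + (S[ID, k] - dss) * np.exp(-dt / td)
        S[IFF, k] = fss + (S[IFF, k] - fss) * np.exp(-dt / tff)
        S[IFS, k] = fss + (S[IFS, k] - fss) * np.exp(-dt / tfs)
        S[IFCAF, k] = fcass + (S[IFCAF, k] - fcass) * np.exp(-dt / tfcaf)
        S[IFCAS, k] = fcass + (S[IFCAS, k] - fcass) * np.exp(-dt / tfcas)
        S[IJCA, k] = fcass + (S[IJCA, k] - fcass) * np.exp(-dt / tjca)
        S[IFFP, k] = fss + (S[IFFP, k] - fss) * np.exp(-dt / tffp)
        S[IFCAFP, k] = fcass + (S[IFCAFP, k] - fcass) * np.exp(-dt / tfcafp)

        f_gate = 0.6 * S[IFF, k] + 0.4 * S[IFS, k]
        fca = Afcaf * S[IFCAF, k] + Afcas * S[IFCAS, k]
        fp_gate = 0.6 * S[IFFP, k] + 0.4 * S[IFS, k]
        fcap = Afcaf * S[IFCAFP, k] + Afcas * S[IFCAS, k]

        Kmn = 0.002
        k2n = 1000.0
        km2n = S[IJCA, k] * 1.0
        tmp = 1.0 + Kmn / cass
        anca = 1.0 / (k2n / km2n + tmp * tmp * tmp * tmp)
        S[INCA, k] = anca * k2n / km2n - (anca * k2n / km2n - S[INCA, k]) * np.exp(-km2n * dt)

        e2v = np.exp(2.0 * vfrt)
        e1v = np.exp(vfrt)
        PhiCaL = 4.0 * vffrt * (cass * e2v - 0.341 * _CAO) / (e2v - 1.0)
        PhiCaNa = vffrt * (0.75 * nass * e1v - 0.75 * _NAO) / (e1v - 1.0)
        PhiCaK = vffrt * (0.75 * kss * e1v - 0.75 * _KO) / (e1v - 1.0)
        PCa = 0.0001 * P[PPCA, k]
        if epi:
            PCa *= 1.2
        PCap = 1.1 * PCa
        PCaNa = 0.00125 * PCa
        PCaK = 3.574e-4 * PCa
        PCaNap = 0.00125 * PCap
        PCaKp = 3.574e-4 * PCap
        fICaLp = fINap
        d_g = S[ID, k]
        nca = S[INCA, k]
        jca = S[IJCA, k]
        ICaL = ((1.0 - fICaLp) * PCa * PhiCaL * d_g * (f_gate * (1.0 - nca) + jca * fca * nca)
                + fICaLp * PCap * PhiCaL * d_g * (fp_gate * (1.0 - nca) + jca * fcap * nca))
        ICaNa = ((1.0 - fICaLp) * PCaNa * PhiCaNa * d_g * (f_gate * (1.0 - nca) + jca * fca * nca)
                 + fICaLp * PCaNap * PhiCaNa * d_g * (fp_gate * (1.0 - nca) + jca * fcap * nca))
        ICaK = ((1.0 - fICaLp) * PCaK * PhiCaK * d_g * (f_gate * (1.0 - nca) + jca * fca * nca)
                + fICaLp * PCaKp * PhiCaK * d_g * (fp_gate * (1.0 - nca) + jca * fcap * nca))

        # --- IKr ---
        xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
        txrf = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869) + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
        txrs = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355) + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))
        Axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
        Axrs = 1.0 - Axrf
        S[IXRF, k] = xrss + (S[IXRF, k] - xrss) * np.exp(-dt / txrf)
        S[IXRS, k] = xrss + (S[IXRS, k] - xrss) * np.exp(-dt / txrs)
        xr = Axrf * S[IXRF, k] + Axrs * S[IXRS, k]
        rkr = 1.0 / ((1.0 + np.exp((v + 55.0) / 75.0)) * (1.0 + np.exp((v - 10.0) / 30.0)))
        GKr = 0.046 * P[PGKR, k]
        if epi:
            GKr *= 1.3
        IKr = GKr * np.sqrt(_KO / 5.4) * xr * rkr * (v - EK)

        # --- IKs ---
        xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
        txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80) + 0.001292 * np.exp(-(v + 210.0) / 230.0))
        txs2 = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0) + 0.0193 * np.exp(-(v + 66.54) / 31.0))
        S[IXS1, k] = xs1ss + (S[IXS1, k] - xs1ss) * np.exp(-dt / txs1)
        S[IXS2, k] = xs1ss + (S[IXS2, k] - xs1ss) * np.exp(-dt / txs2)
        KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
        GKs = 0.0034 * P[PGKS, k]
        if epi:
            GKs *= 1.4
        IKs = GKs * KsCa * S[IXS1, k] * S[IXS2, k] * (v - EKs)

        # --- IK1 ---
        xk1ss = 1.0 / (1.0 + np.exp(-(v + 2.5538 * _KO + 144.59) / (1.5692 * _KO + 3.8115)))
        txk1 = 122.2 / (np.exp(-(v + 127.2) / 20.36) + np.exp((v + 236.8) / 69.33))
        S[IXK1, k] = xk1ss + (S[IXK1, k] - xk1ss) * np.exp(-dt / txk1)
        rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * _KO) / 9.493))
        GK1 = 0.1908 * P[PGK1, k]
        if epi:
            GK1 *= 1.2
        IK1 = GK1 * np.sqrt(_KO) * rk1 * S[IXK1, k] * (v - EK)

        # --- INaCa (myoplasmic and subspace) ---
        kna1 = 15.0
        kna2 = 5.0
        kna3 = 88.12
        kasymm = 12.5
        wna = 6.0e4
        wca = 6.0e4
        wnaca = 5.0e3
        kcaon = 1.5e6
        kcaoff = 5.0e3
        qna = 0.5224
        qca = 0.1670
        hca = np.exp(qca * vfrt)
        hna = np.exp(qna * vfrt)
        KmCaAct = 150.0e-6
        Gncx = 0.0008 * P[PGNCX, k]
        if epi:
            Gncx *= 1.1

        # myoplasmic
        h1 = 1.0 + nai / kna3 * (1.0 + hna)
        h2 = (nai * hna) / (kna3 * h1)
        h3 = 1.0 / h1
        h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
        h5 = nai * nai / (h4 * kna1 * kna2)
        h6 = 1.0 / h4
        h7 = 1.0 + _NAO / kna3 * (1.0 + 1.0 / hna)
        h8 = _NAO / (kna3 * hna * h7)
        h9 = 1.0 / h7
        h10 = kasymm + 1.0 + _NAO / kna1 * (1.0 + _NAO / kna2)
        h11 = _NAO * _NAO / (h10 * kna1 * kna2)
        h12 = 1.0 / h10
        k1 = h12 * _CAO * kcaon
        k2 = kcaoff
        k3p = h9 * wca
        k3pp = h8 * wnaca
        k3 = k3p + k3pp
        k4p = h3 * wca / hca
        k4pp = h2 * wnaca
        k4 = k4p + k4pp
        k5 = kcaoff
        k6 = h6 * cai * kcaon
        k7 = h5 * h2 * wna
        k8 = h8 * h11 * wna
        x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
        x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
        x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
        x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
        E1 = x1 / (x1 + x2 + x3 + x4)
        E2 = x2 / (x1 + x2 + x3 + x4)
        E3 = x3 / (x1 + x2 + x3 + x4)
        E4 = x4 / (x1 + x2 + x3 + x4)
        allo = 1.0 / (1.0 + (KmCaAct / cai) * (KmCaAct / cai))
        JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
        JncxCa = E2 * k2 - E1 * k1
        INaCa_i = 0.8 * Gncx * allo * (JncxNa + 2.0 * JncxCa)

        # subspace
        h1 = 1.0 + nass / kna3 * (1.0 + hna)
        h2 = (nass * hna) / (kna3 * h1)
        h3 = 1.0 / h1
        h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
        h5 = nass * nass / (h4 * kna1 * kna2)
        h6 = 1.0 / h4
        k4p = h3 * wca / hca
        k4pp = h2 * wnaca
        k4 = k4p + k4pp
        k6 = h6 * cass * kcaon
        k7 = h5 * h2 * wna
        x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
        x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
        x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
        x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
        E1 = x1 / (x1 + x2 + x3 + x4)
        E2 = x2 / (x1 + x2 + x3 + x4)
        E3 = x3 / (x1 + x2 + x3 + x4)
        E4 = x4 / (x1 + x2 + x3 + x4)
        allo = 1.0 / (1.0 + (KmCaAct / cass) * (KmCaAct / cass))
        JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
        JncxCa = E2 * k2 - E1 * k1
        INaCa_ss = 0.2 * Gncx * allo * (JncxNa + 2.0 * JncxCa)

        # --- INaK ---
        k1p = 949.5
        k1m = 182.4
        k2p = 687.2
        k2m = 39.4
        k3p_ = 1899.0
        k3m = 79300.0
        k4p_ = 639.0
        k4m = 40.0
        Knai = 9.073 * np.exp(-0.1550 * vfrt / 3.0)
        Knao = 27.78 * np.exp((1.0 + 0.1550) * vfrt / 3.0)
        Kki = 0.5
        Kko = 0.3582
        MgADP = 0.05
        MgATP = 9.8
        Kmgatp = 1.698e-7
        H = 1.0e-7
        eP = 4.2
        Khp = 1.698e-7
        Knap = 224.0
        Kxkur = 292.0
        Pph = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
        t1 = 1.0 + nai / Knai
        t2 = 1.0 + ki / Kki
        t3 = 1.0 + _NAO / Knao
        t4 = 1.0 + _KO / Kko
        a1 = k1p * (nai / Knai) ** 3 / (t1 * t1 * t1 + t2 * t2 - 1.0)
        b1 = k1m * MgADP
        a2 = k2p
        b2 = k2m * (_NAO / Knao) ** 3 / (t3 * t3 * t3 + t4 * t4 - 1.0)
        a3 = k3p_ * (_KO / Kko) ** 2 / (t3 * t3 * t3 + t4 * t4 - 1.0)
        b3 = k3m * Pph * H / (1.0 + MgATP / Kmgatp)
        a4 = k4p_ * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
        b4 = k4m * (ki / Kki) ** 2 / (t1 * t1 * t1 + t2 * t2 - 1.0)
        x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
        x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
        x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
        x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
        E1 = x1 / (x1 + x2 + x3 + x4)
        E2 = x2 / (x1 + x2 + x3 + x4)
        E3 = x3 / (x1 + x2 + x3 + x4)
        E4 = x4 / (x1 + x2 + x3 + x4)
        JnakNa = 3.0 * (E1 * a3 - E2 * b3)
        JnakK = 2.0 * (E4 * b1 - E3 * a1)
        Pnak = 30.0 * P[PPNAK, k]
        if epi:
            Pnak *= 0.9
        INaK = Pnak * (JnakNa + JnakK)

        # --- background and pump currents ---
        xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
        GKb = 0.003 * P[PGKB, k]
        if epi:
            GKb *= 0.6
        IKb = GKb * xkb * (v - EK)
        INab = 3.75e-10 * vffrt * (nai * e1v - _NAO) / (e1v - 1.0)
        ICab = 2.5e-8 * 4.0 * vffrt * (cai * e2v - 0.341 * _CAO) / (e2v - 1.0)
        IpCa = 0.0005 * cai / (0.0005 + cai)

        # --- diffusion fluxes between subspace and myoplasm ---
        JdiffNa = (nass - nai) / 2.0
        JdiffK = (kss - ki) / 2.0
        Jdiff = (cass - cai) / 0.2

        # --- SR release (RyR) ---
        bt = 4.75
        a_rel = 0.5 * bt
        Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
        Jrel_inf *= P[PJREL, k]
        tau_rel = bt / (1.0 + 0.0123 / cajsr)
        if tau_rel < 0.001:
            tau_rel = 0.001
        S[IJRELNP, k] = Jrel_inf + (S[IJRELNP, k] - Jrel_inf) * np.exp(-dt / tau_rel)
        btp = 1.25 * bt
        a_relp = 0.5 * btp
        Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
        Jrel_infp *= P[PJREL, k]
        tau_relp = btp / (1.0 + 0.0123 / cajsr)
        if tau_relp < 0.001:
            tau_relp = 0.001
        S[IJRELP, k] = Jrel_infp + (S[IJRELP, k] - Jrel_infp) * np.exp(-dt / tau_relp)
        fJrelp = fINap
        Jrel = (1.0 - fJrelp) * S[IJRELNP, k] + fJrelp * S[IJRELP, k]

        # --- SR uptake (SERCA) and translocation ---
        Jupnp = 0.004375 * cai / (cai + 0.00092)
        Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
        if epi:
            Jupnp *= 1.3
            Jupp *= 1.3
        Jupnp *= P[PJUP, k]
        Jupp *= P[PJUP, k]
        fJupp = fINap
        Jleak = 0.0039375 * cansr / 15.0
        Jup = (1.0 - fJupp) * Jupnp + fJupp * Jupp - Jleak
        Jtr = (cansr - cajsr) / 100.0

        # --- concentration updates ---
        cmdnmax = 0.05 * P[PCMDN, k]
        if epi:
            cmdnmax *= 1.3
        kmcmdn = 0.00238
        trpnmax = 0.07
        kmtrpn = 0.0005
        BSRmax = 0.047
        KmBSR = 0.00087
        BSLmax = 1.124
        KmBSL = 0.0087
        csqnmax = 10.0
        kmcsqn = 0.8

        dnai = -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * _ACAP / (_F * _VMYO) + JdiffNa * _VSS / _VMYO
        dnass = -(ICaNa + 3.0 * INaCa_ss) * _ACAP / (_F * _VSS) - JdiffNa
        dki = (-(Ito + IKr + IKs + IK1 + IKb + istim[k] - 2.0 * INaK) * _ACAP / (_F * _VMYO)
               + JdiffK * _VSS / _VMYO)
        dkss = -ICaK * _ACAP / (_F * _VSS) - JdiffK
        t5 = kmcmdn + cai
        t6 = kmtrpn + cai
        Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (t5 * t5) + trpnmax * kmtrpn / (t6 * t6))
        dcai = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * _ACAP / (2.0 * _F * _VMYO)
                       - Jup * _VNSR / _VMYO + Jdiff * _VSS / _VMYO)
        t7 = KmBSR + cass
        t8_ = KmBSL + cass
        Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (t7 * t7) + BSLmax * KmBSL / (t8_ * t8_))
        dcass = Bcass * (-(ICaL - 2.0 * INaCa_ss) * _ACAP / (2.0 * _F * _VSS)
                         + Jrel * _VJSR / _VSS - Jdiff)
        dcansr = Jup - Jtr * _VJSR / _VNSR
        t9 = kmcsqn + cajsr
        Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (t9 * t9))
        dcajsr = Bcajsr * (Jtr - Jrel)

        Itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
                + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + istim[k])

        S[IV, k] = v - dt * Itot
        S[INAI, k] = nai + dt * dnai
        S[INASS, k] = nass + dt * dnass
        S[IKI, k] = ki + dt * dki
        S[IKSS, k] = kss + dt * dkss
        S[ICAI, k] = cai + dt * dcai
        S[ICASS, k] = cass + dt * dcass
        S[ICANSR, k] = cansr + dt * dcansr
        S[ICAJSR, k] = cajsr + dt * dcajsr
        S[ICAMKT, k] = S[ICAMKT, k] + dt * dCaMKt
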