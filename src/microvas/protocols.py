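"""Motion-probing gradient waveforms and acquisition protocols.

Two waveform families are supported, both expressed in the effective-gradient
convention (the 180-degree refocusing pulse folded into the sign of G):

* NC -- non-compensated monopolar PGSE: lobes +G on [0, delta] and -G on
  [Delta, Delta + delta]. Zeroth gradient moment vanishes, so stationary spins
  are refocused. Closed-form b = gamma^2 G^2 delta^2 (Delta - delta/3);
  diffusion time Delta - delta/3.
* FC -- flow-compensated bipolar: lobe pairs [+G, -G] of half-period tau
  before and [-G, +G] after the refocusing midpoint, separated by Delta.
  Both the zeroth and the first gradient moments vanish, so spins flowing at
  constant velocity (ballistic regime) are refocused too. Closed-form
  b = (4/3) gamma^2 G^2 tau^3; diffusion time tau.

Waveforms are sampled at dt = 10 us; the closed forms are unit-tested against
numerical integration of b = gamma^2 int (int G)^2 dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Waveform",
    "ProtocolSpec",
    "nc_waveform",
    "fc_waveform",
    "direction_set",
    "build_protocol",
    "GAMMA_RAD_S_T",
    "DT_S",
    "IVIM_B_VALUES",
    "INVIVO_B_VALUES",
    "INVIVO_DELTA_MS",
    "INVIVO_DELTA_SEP_MS",
]

#: Proton gyromagnetic ratio, rad / (s T).
GAMMA_RAD_S_T = 267.52218744e6

#: Waveform sampling interval, s (10 us).
DT_S = 1.0e-5

#: Standard IVIM-style b shell list, s/mm^2.
IVIM_B_VALUES = (0.0, 10.0, 20.0, 40.0, 70.0, 100.0)

#: Printed in vivo acquisition tables: b (s/mm^2), delta (ms), Delta (ms).
INVIVO_B_VALUES = (0.0, 10.0, 20.0, 40.0, 70.0, 100.0, 500.0, 1000.0, 1250.0, 1500.0)
INVIVO_DELTA_MS = (0.00, 2.06, 2.57, 3.37, 4.18, 4.82, 11.97, 16.15, 18.77, 21.12)
INVIVO_DELTA_SEP_MS = (0.00, 31.34, 31.85, 32.65, 33.47, 34.10, 25.23, 29.41, 32.03, 34.38)

_PAD_S = 1.0e-3  # TE padding beyond the last gradient lobe


def _round_samples(t_s: float) -> int:
    return int(round(t_s / DT_S))


@dataclass(frozen=True)
class Waveform:
    """A sampled effective gradient waveform along one direction.

    ``profile`` holds the unit-amplitude shape (+1/0/-1 per sample over
    [i*dt, (i+1)*dt)); the physical gradient is ``G * profile`` in T/m.
    """

    kind: str                      # "NC" | "FC"
    profile: np.ndarray            # unit-amplitude samples
    G: float                       # gradient amplitude, T/m
    b: float                       # nominal b-value, s/mm^2
    delta_ms: float | None = None
    Delta_ms: float | None = None
    tau_ms: float | None = None
    dt: float = DT_S

    def __post_init__(self):
        object.__setattr__(self, "profile", np.asarray(self.profile, dtype=float))

    @property
    def g(self) -> np.ndarray:
        """Sampled gradient, T/m."""
        return self.G * self.profile

    @property
    def n_samples(self) -> int:
        return len(self.profile)

    @property
    def te_ms(self) -> float:
        """Echo time: minimal window containing the waveform plus padding."""
        return self.n_samples * self.dt * 1e3

    @property
    def diffusion_time_ms(self) -> float:
        if self.kind == "NC":
            return self.Delta_ms - self.delta_ms / 3.0
        return self.tau_ms

    # -- moments and numeric b ---------------------------------------------
    def moment0(self) -> float:
        """Zeroth gradient moment, T s / m (vanishes for NC and FC)."""
        return float(np.sum(self.g) * self.dt)

    def moment1(self) -> float:
        """First gradient moment, T s^2 / m (vanishes for FC)."""
        t = (np.arange(self.n_samples) + 0.5) * self.dt
        return float(np.sum(t * self.g) * self.dt)

    def b_numeric(self) -> float:
        """b from numerical integration of gamma^2 int (int G dt')^2 dt, s/mm^2."""
        cums = np.cumsum(self.g) * self.dt
        f_mid = cums - self.g * self.dt / 2.0  # F at sample midpoints
        b_si = GAMMA_RAD_S_T**2 * np.sum(f_mid**2) * self.dt  # s/m^2
        return b_si * 1e-6


def nc_waveform(delta_ms: float, Delta_ms: float, b_s_mm2: float) -> Waveform:
    """Monopolar PGSE waveform with duration/separation delta/Delta (ms)."""
    if not 0 < delta_ms <= Delta_ms:
        raise ValueError("require 0 < delta <= Delta")
    if b_s_mm2 < 0:
        raise ValueError("b must be >= 0")
    nd = _round_samples(delta_ms * 1e-3)
    nD = _round_samples(Delta_ms * 1e-3)
    n = nD + nd + _round_samples(_PAD_S)
    profile = np.zeros(n)
    profile[:nd] = 1.0
    profile[nD : nD + nd] = -1.0
    # invert G from the realised (sample-aligned) timings so the numeric b
    # integral matches the closed form regardless of grid rounding
    delta, Delta = nd * DT_S, nD * DT_S
    b_si = b_s_mm2 * 1e6
    G = np.sqrt(b_si / (GAMMA_RAD_S_T**2 * delta**2 * (Delta - delta / 3.0)))
    return Waveform(
        kind="NC", profile=profile, G=float(G), b=float(b_s_mm2),
        delta_ms=delta_ms, Delta_ms=Delta_ms,
    )


def fc_waveform(tau_ms: float, Delta_ms: float, b_s_mm2: float) -> Waveform:
    """Flow-compensated bipolar waveform with half-period tau and pair
    separation Delta (ms); requires 2 tau <= Delta."""
    if not 0 < 2 * tau_ms <= Delta_ms:
        raise ValueError("require 0 < 2*tau <= Delta")
    if b_s_mm2 < 0:
        raise ValueError("b must be >= 0")
    nt = _round_samples(tau_ms * 1e-3)
    nD = max(_round_samples(Delta_ms * 1e-3), 2 * nt)  # pairs must not overlap
    n = nD + 2 * nt + _round_samples(_PAD_S)
    profile = np.zeros(n)
    profile[:nt] = 1.0
    profile[nt : 2 * nt] = -1.0
    profile[nD : nD + nt] = -1.0
    profile[nD + nt : nD + 2 * nt] = 1.0
    tau = nt * DT_S  # realised (sample-aligned) half-period
    b_si = b_s_mm2 * 1e6
    G = np.sqrt(3.0 * b_si / (4.0 * GAMMA_RAD_S_T**2 * tau**3))
    return Waveform(
        kind="FC", profile=profile, G=float(G), b=float(b_s_mm2),
        tau_ms=tau_ms, Delta_ms=Delta_ms,
    )


def direction_set(n: int = 15, seed: int | None = 0, n_iter: int = 2000) -> np.ndarray:
    """n approximately uniformly distributed unit gradient directions.

    Electrostatic-repulsion optimisation with antipodal symmetry (each
    direction repels both the others and their antipodes), deterministic for a
    fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return x
    step = 0.05
    for it in range(n_iter):
        diff_m = x[:, None, :] - x[None, :, :]
        diff_p = x[:, None, :] + x[None, :, :]
        dm = np.linalg.norm(diff_m, axis=2)
        dp = np.linalg.norm(diff_p, axis=2)
        np.fill_diagonal(dm, np.inf)
        np.fill_diagonal(dp, np.inf)
        force = (diff_m / dm[..., None] ** 3).sum(axis=1) + (
            diff_p / dp[..., None] ** 3
        ).sum(axis=1)
        # keep only the tangential component
        force -= (force * x).sum(axis=1, keepdims=True) * x
        x = x + step * force / max(n, 1)
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        if it == n_iter // 2:
            step *= 0.2
    return x


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered list of (waveform, direction) measurements.

    ``measurements`` holds (waveform_index, direction_index) pairs into
    ``waveforms`` and ``directions``. When ``averaged`` is set, analyses
    collapse the direction axis by the arithmetic mean at fixed waveform.
    """

    name: str
    waveforms: tuple[Waveform, ...]
    directions: np.ndarray
    measurements: tuple[tuple[int, int], ...]
    averaged: bool = True
    snr: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        if not np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-8):
            raise ValueError("directions must be unit norm")
        object.__setattr__(self, "directions", d)
        if not any(self.waveforms[wi].b == 0 for wi, _ in self.measurements):
            raise ValueError("protocol must include b=0 entries")

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    @property
    def b_values(self) -> np.ndarray:
        """b per measurement, s/mm^2."""
        return np.array([self.waveforms[wi].b for wi, _ in self.measurements])

    @property
    def unique_b(self) -> np.ndarray:
        return np.unique(self.b_values)

    @property
    def n_averaged(self) -> int:
        """Number of measurements after directional averaging (one per
        waveform)."""
        return len(self.waveforms)

    def averaging_groups(self) -> list[np.ndarray]:
        """Measurement indices grouped by waveform, in waveform order."""
        wi = np.array([w for w, _ in self.measurements])
        return [np.flatnonzero(wi == k) for k in range(len(self.waveforms))]

    def to_table(self) -> "np.ndarray":
        """Plain-text-friendly table: columns b, kind(0=NC,1=FC), delta, Delta,
        tau (ms; -1 where not applicable), gx, gy, gz."""
        rows = []
        for wi, di in self.measurements:
            w = self.waveforms[wi]
            rows.append(
                [
                    w.b,
                    0.0 if w.kind == "NC" else 1.0,
                    w.delta_ms if w.delta_ms is not None else -1.0,
                    w.Delta_ms if w.Delta_ms is not None else -1.0,
                    w.tau_ms if w.tau_ms is not None else -1.0,
                    *self.directions[di],
                ]
            )
        return np.array(rows)


_RICH_N_B = 20


def _expand(waveforms: list[Waveform], n_dir: int) -> tuple:
    return tuple((wi, di) for wi in range(len(waveforms)) for di in range(n_dir))


def build_protocol(
    name: str,
    Delta_ms: float = 30.0,
    delta_ms: float = 6.0,
    tau_ms: float = 10.0,
    n_directions: int = 15,
    averaged: bool = True,
    direction_seed: int = 0,
) -> ProtocolSpec:
    """Construct one of the named acquisition protocols.

    name in {"NC", "FC", "hybrid", "richNC", "richFC", "hybrid-rich",
    "in-vivo"}. NC-family timings are set by (delta_ms, Delta_ms), FC-family
    by (tau_ms, Delta_ms); the standard timing variants are Delta in {30, 50}
    ms for NC and tau in {3, 10} ms for FC. "rich" protocols sample 20 equally
    spaced b in [0, 100] s/mm^2; hybrids alternate NC and FC entries over the
    parent b list; "in-vivo" reproduces the printed 10-shell b/delta/Delta
    acquisition tables.
    """
    dirs = direction_set(n_directions, seed=direction_seed)
    if name == "NC":
        wfs = [nc_waveform(delta_ms, Delta_ms, b) for b in IVIM_B_VALUES]
    elif name == "FC":
        wfs = [fc_waveform(tau_ms, Delta_ms, b) for b in IVIM_B_VALUES]
    elif name == "hybrid":
        wfs = [
            nc_waveform(delta_ms, Delta_ms, b) if i % 2 == 0
            else fc_waveform(tau_ms, Delta_ms, b)
            for i, b in enumerate(IVIM_B_VALUES)
        ]
    elif name == "richNC":
        bs = np.linspace(0.0, 100.0, _RICH_N_B)
        wfs = [nc_waveform(delta_ms, Delta_ms, b) for b in bs]
    elif name == "richFC":
        bs = np.linspace(0.0, 100.0, _RICH_N_B)
        wfs = [fc_waveform(tau_ms, Delta_ms, b) for b in bs]
    elif name == "hybrid-rich":
        bs = np.linspace(0.0, 100.0, _RICH_N_B)
        wfs = [
            nc_waveform(delta_ms, Delta_ms, b) if i % 2 == 0
            else fc_waveform(tau_ms, Delta_ms, b)
            for i, b in enumerate(bs)
        ]
    elif name == "in-vivo":
        wfs = []
        for b, d, D in zip(INVIVO_B_VALUES, INVIVO_DELTA_MS, INVIVO_DELTA_SEP_MS):
            if b == 0:
                # scanner reports zero timings at b=0; use the shortest
                # nonzero timing pair for the (zero-amplitude) waveform
                d, D = INVIVO_DELTA_MS[1], INVIVO_DELTA_SEP_MS[1]
            wfs.append(nc_waveform(d, D, b))
    else:
        raise ValueError(f"unknown protocol name: {name!r}")
    return ProtocolSpec(
        name=name,
        waveforms=tuple(wfs),
        directions=dirs,
        measurements=_expand(wfs, n_directions),
        averaged=averaged,
    )
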