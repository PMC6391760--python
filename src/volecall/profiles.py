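"""Species profiles and the generative model for distress-call parameters.

The package ships reference profiles for three groups of red-backed voles —
the Tien Shan vole (*Myodes centralis*), the bank vole (*M. glareolus*) and
their F1 hybrids — each described by the published group means and standard
errors of five call parameters: duration, maximum fundamental frequency,
frequency-modulation range, 50% energy quartile and spectral entropy.
Per-call parameters are drawn independently from normal distributions with
SD reconstructed as SE * sqrt(n_reference); no cross-parameter covariance is
modelled (a documented limitation of the generator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

STRUCTURES = ("harmonic", "noise", "mixed")

#: Measured spectral entropy of a synthesised call with noise_fraction = 0
#: resp. 1 at study-typical durations (calibration constants for the
#: entropy -> noise_fraction map of mixed calls; see docs/methods.md).
ENTROPY_PURE_HARMONIC = 0.05
ENTROPY_PURE_NOISE = 0.62


@dataclass(frozen=True)
class SpeciesProfile:
    """Generative distribution of call parameters for one group.

    Each acoustic parameter is a ``(mean, standard_error)`` pair on the scale
    noted in the field name (seconds / Hz / dimensionless entropy in (0, 1)).
    ``n_calls_reference`` is the sample size behind those standard errors and
    is used to reconstruct per-call SDs as ``SE * sqrt(n)``.
    """

    name: str
    n_calls_reference: int
    duration_s: tuple[float, float]
    f0max_hz: tuple[float, float]
    modulation_range_hz: tuple[float, float]
    q50_hz: tuple[float, float]
    entropy: tuple[float, float]
    structure_mix: dict[str, float]
    harmonic_count_range: tuple[int, int] = (3, 10)
    noise_to_harmonic_energy: float = 1.0

    def __post_init__(self) -> None:
        if self.n_calls_reference < 1:
            raise ValueError("n_calls_reference must be positive")
        for pname in ("duration_s", "f0max_hz", "modulation_range_hz", "q50_hz"):
            mean, se = getattr(self, pname)
            if pname != "modulation_range_hz" and mean <= 0:
                raise ValueError(f"{pname} mean must be > 0")
            if se <= 0:
                raise ValueError(f"{pname} SE must be > 0")
        e_mean, e_se = self.entropy
        if not 0.0 < e_mean < 1.0:
            raise ValueError("entropy mean must lie in (0, 1)")
        if e_se <= 0:
            raise ValueError("entropy SE must be > 0")
        if set(self.structure_mix) != set(STRUCTURES):
            raise ValueError(f"structure_mix must have keys {STRUCTURES}")
        if abs(sum(self.structure_mix.values()) - 1.0) > 1e-9:
            raise ValueError("structure_mix must sum to 1")
        if any(v < 0 for v in self.structure_mix.values()):
            raise ValueError("structure_mix proportions must be >= 0")
        lo, hi = self.harmonic_count_range
        if not (3 <= lo <= hi <= 10):
            raise ValueError("harmonic_count_range must lie within [3, 10]")
        if self.noise_to_harmonic_energy < 0:
            raise ValueError("noise_to_harmonic_energy must be >= 0")

    def sd(self, parameter: str) -> float:
        """Per-call SD of *parameter*, reconstructed as SE * sqrt(n)."""
        _, se = getattr(self, parameter)
        return se * math.sqrt(self.n_calls_reference)


@dataclass(frozen=True)
class CallSpec:
    """Ground-truth description of a single call to be synthesised.

    ``q50_target_hz`` and ``entropy_target`` are the drawn population values
    the synthesiser aims at: the spectral centre of the call and the tonal
    vs. noisy balance (the latter realised through ``noise_fraction``).
    """

    duration_s: float
    f0max_hz: float
    modulation_range_hz: float
    n_harmonics: int
    structure: str
    noise_fraction: float
    q50_target_hz: float
    entropy_target: float
    attack_fraction: float = 0.1
    decay_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if not self.f0max_hz > self.modulation_range_hz >= 0:
            raise ValueError("need f0max_hz > modulation_range_hz >= 0 "
                             "(minimum f0 must stay positive)")
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        nf = self.noise_fraction
        if self.structure == "harmonic" and nf != 0.0:
            raise ValueError("harmonic calls have noise_fraction = 0")
        if self.structure == "noise" and nf != 1.0:
            raise ValueError("noise calls have noise_fraction = 1")
        if self.structure == "mixed" and not 0.0 < nf < 1.0:
            raise ValueError("mixed calls need noise_fraction in (0, 1)")
        if not 3 <= self.n_harmonics <= 10:
            raise ValueError("n_harmonics must lie in [3, 10]")
        if not (0 <= self.attack_fraction and 0 <= self.decay_fraction
                and self.attack_fraction + self.decay_fraction <= 1):
            raise ValueError("attack/decay fractions must be >= 0 and sum <= 1")


def default_profiles() -> dict[str, SpeciesProfile]:
    """Reference profiles for the three study groups.

    Means and standard errors are the published group statistics (duration in
    s, frequencies in Hz, entropy dimensionless); reference n are 118 (Tien
    Shan), 108 (hybrids) and 78 (bank voles).  Structure-class proportions
    are not published per group; the defaults put roughly 43% of calls in the
    voiced classes (harmonic + mixed) overall — consistent with the published
    ANOVA degrees of freedom for the fundamental-frequency parameters — with
    the bank voles noisiest.
    """
    return {
        "tien_shan": SpeciesProfile(
            name="tien_shan",
            n_calls_reference=118,
            duration_s=(0.027, 0.001),
            f0max_hz=(3800.0, 100.0),
            modulation_range_hz=(2500.0, 100.0),
            q50_hz=(4000.0, 100.0),
            entropy=(0.520, 0.005),
            structure_mix={"harmonic": 0.15, "mixed": 0.35, "noise": 0.50},
        ),
        "hybrid": SpeciesProfile(
            name="hybrid",
            n_calls_reference=108,
            duration_s=(0.023, 0.001),
            f0max_hz=(3200.0, 100.0),
            modulation_range_hz=(1600.0, 100.0),
            q50_hz=(7900.0, 100.0),
            entropy=(0.586, 0.008),
            structure_mix={"harmonic": 0.10, "mixed": 0.35, "noise": 0.55},
        ),
        "bank": SpeciesProfile(
            name="bank",
            n_calls_reference=78,
            duration_s=(0.054, 0.004),
            f0max_hz=(1500.0, 100.0),
            modulation_range_hz=(600.0, 100.0),
            q50_hz=(6800.0, 100.0),
            entropy=(0.637, 0.004),
            structure_mix={"harmonic": 0.05, "mixed": 0.30, "noise": 0.65},
        ),
    }


def _noise_fraction_for(structure: str, entropy_target: float,
                        scale: float) -> float:
    if structure == "harmonic":
        return 0.0
    if structure == "noise":
        return 1.0
    span = ENTROPY_PURE_NOISE - ENTROPY_PURE_HARMONIC
    nf = scale * (entropy_target - ENTROPY_PURE_HARMONIC) / span
    return float(np.clip(nf, 0.02, 0.98))


def sample_call_specs(profile: SpeciesProfile, n: int,
                      seed: int | np.random.Generator) -> list[CallSpec]:
    """Draw *n* reproducible :class:`CallSpec` from a species profile.

    Each parameter is drawn independently from a normal distribution with the
    profile mean and SD = SE * sqrt(n_reference), then truncated to its
    physical validity range (duration >= 2 ms, frequencies > 0, entropy in
    (0.01, 0.99), modulation range below f0max).  The structure class is
    drawn from the profile's mix; the noise fraction of mixed calls is set
    from the drawn entropy target through a fixed monotone calibration.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    def draw(pname: str) -> np.ndarray:
        mean, _ = getattr(profile, pname)
        return rng.normal(mean, profile.sd(pname), size=n)

    duration = np.clip(draw("duration_s"), 0.002, None)
    f0max = np.clip(draw("f0max_hz"), 300.0, None)
    mod = np.clip(draw("modulation_range_hz"), 0.0, 0.95 * f0max)
    q50 = np.clip(draw("q50_hz"), 200.0, 10_000.0)
    entropy = np.clip(draw("entropy"), 0.01, 0.99)
    lo, hi = profile.harmonic_count_range
    n_harm = rng.integers(lo, hi + 1, size=n)
    mix = np.array([profile.structure_mix[s] for s in STRUCTURES])
    structures = rng.choice(STRUCTURES, size=n, p=mix)

    return [
        CallSpec(
            duration_s=float(duration[i]),
            f0max_hz=float(f0max[i]),
            modulation_range_hz=float(mod[i]),
            n_harmonics=int(n_harm[i]),
            structure=str(structures[i]),
            noise_fraction=_noise_fraction_for(
                str(structures[i]), float(entropy[i]),
                profile.noise_to_harmonic_energy),
            q50_target_hz=float(q50[i]),
            entropy_target=float(entropy[i]),
        )
        for i in range(n)
    ]


def specs_to_frame(specs: list[CallSpec], group: str | None = None) -> pd.DataFrame:
    """Tabulate call specs as one row per call (ground-truth table).

    The drawn population targets appear under the same column names the
    measurement stage uses (``duration_s``, ``q50_hz``, ``entropy``) so the
    table can feed the statistics chain directly.
    """
    rows = []
    for i, s in enumerate(specs):
        d = asdict(s)
        d["q50_hz"] = d.pop("q50_target_hz")
        d["entropy"] = d.pop("entropy_target")
        d["call_id"] = i
        if group is not None:
            d["group"] = group
        rows.append(d)
    return pd.DataFrame(rows)
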