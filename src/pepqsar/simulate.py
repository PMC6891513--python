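"""Synthetic data generators with known ground truth.

Two generators mirror the statistical structure the analysis assumes:

* :func:`gen_peptide_dataset` — peptide/activity tables whose activity
  is an exact linear function of the encoded descriptor features plus
  Gaussian noise, emulating the shape of the ORAC activity database
  (variable lengths, real-valued activities, negatives allowed).
* :func:`gen_fluorescence_experiment` — kinetic fluorescence reads at
  0, 10, ..., 60 min per dose, scaled so the resulting CAA units obey
  an exact median-effect law with a stated EC50 and slope, then
  perturbed by multiplicative lognormal noise.

Both are pure functions of their spec (including its seed), so every
downstream recovery test has exact ground truth to compare against.
The CAA law is imposed analytically on the AUC ratio, which makes the
EC50 ground truth independent of the control-curve shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import (
    DescriptorScale,
    EncodingSpec,
    STANDARD_AMINO_ACIDS,
    encode_set,
    load_scale,
)
from .qsar import PeptideRecord


@dataclass(frozen=True)
class PeptideSimSpec:
    """Configuration of the peptide-activity generator.

    ``noise_sd`` is expressed as a fraction of the standard deviation
    of the noiseless signal (0.1 = 10% relative noise).  ``true_beta``
    may fix the coefficient vector in encoded-feature space; when None
    a standard-normal vector is drawn from the seed.
    """

    n: int = 60
    length_range: tuple[int, int] = (2, 26)
    true_beta: tuple[float, ...] | None = None
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad length_range {self.length_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_peptide_dataset(
    spec: PeptideSimSpec,
    encoding: EncodingSpec | None = None,
    scale: DescriptorScale | None = None,
) -> tuple[list[PeptideRecord], dict]:
    """Draw random peptides and descriptor-linear activities.

    Sequences are uniform over the 20-letter alphabet with lengths
    uniform in ``length_range``; ``activity = beta . encode(seq) + eps``
    with ``eps ~ N(0, noise_sd * sd(signal))``.

    Returns
    -------
    (records, truth)
        ``truth`` holds the coefficient vector (``beta``), the
        noiseless signal (``signal``), its standard deviation
        (``signal_sd``) and the realised noise draw (``noise``).
    """
    if encoding is None:
        encoding = EncodingSpec()
    if scale is None:
        scale = load_scale(encoding.scale_ref)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n)
    alphabet = np.array(list(STANDARD_AMINO_ACIDS))
    seqs = ["".join(rng.choice(alphabet, size=L)) for L in lengths]
    X, seqs = encode_set(seqs, encoding, scale)
    p = X.shape[1]
    if spec.true_beta is not None:
        beta = np.asarray(spec.true_beta, dtype=float)
        if beta.shape != (p,):
            raise ValueError(f"true_beta must have length {p}, got {beta.shape}")
    else:
        beta = rng.standard_normal(p)
    signal = X @ beta
    signal_sd = float(signal.std(ddof=1)) if spec.n > 1 else 0.0
    noise = rng.normal(0.0, spec.noise_sd * signal_sd, size=spec.n) if spec.noise_sd > 0 else np.zeros(spec.n)
    activities = signal + noise
    records = [PeptideRecord(s, float(a)) for s, a in zip(seqs, activities)]
    truth = {
        "beta": beta,
        "signal": signal,
        "signal_sd": signal_sd,
        "noise": noise,
        "encoding": encoding,
        "scale": scale.name,
        "seed": spec.seed,
    }
    return records, truth


@dataclass(frozen=True)
class FluorescenceExperiment:
    """Kinetic fluorescence reads: one control curve plus one curve per dose."""

    times: tuple[float, ...]
    control_curve: tuple[float, ...]
    sample_curves: dict[float, tuple[float, ...]] = field(repr=False)

    def __post_init__(self):
        if len(self.times) < 2:
            raise ValueError("need at least two time points")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        for dose, curve in self.sample_curves.items():
            if len(curve) != len(self.times):
                raise ValueError(f"curve for dose {dose} does not match the time grid")

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(sorted(self.sample_curves))

    def to_frame(self) -> pd.DataFrame:
        """The CSV dialect the assay readers consume: time, control, one column per dose."""
        data = {"time": self.times, "control": self.control_curve}
        for dose in self.doses:
            data[f"{dose:g}"] = self.sample_curves[dose]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class CurveSimSpec:
    """Configuration of the fluorescence-experiment generator.

    Defaults place five two-fold-spaced doses around an EC50 of
    0.04 mg/mL with median-effect slope 1.5 and 2% multiplicative
    noise; the control decays exponentially at ``control_decay`` per
    minute from ``control_f0`` fluorescence units.
    """

    doses: tuple[float, ...] = (0.01, 0.02, 0.04, 0.08, 0.16)
    ec50: float = 0.04
    slope: float = 1.5
    control_f0: float = 10000.0
    control_decay: float = 0.02
    noise_frac: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.slope == 0:
            raise ValueError("slope must be non-zero")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")


def median_effect_caa(dose: float, ec50: float, slope: float) -> float:
    """Exact median-effect CAA at a dose: logit10(CAA/100) = m (log10 D - log10 EC50)."""
    ratio = (dose / ec50) ** slope
    return 100.0 * ratio / (1.0 + ratio)


def gen_fluorescence_experiment(spec: CurveSimSpec) -> tuple[FluorescenceExperiment, float]:
    """Generate a kinetic experiment whose CAA units follow an exact median-effect law.

    The time grid is 0, 10, ..., 60 min.  The control is a decreasing
    exponential; the sample curve at dose D is the control scaled by
    ``1 - CAA(D)/100`` (which fixes the AUC ratio, hence the CAA,
    analytically), then multiplied pointwise by lognormal noise of
    level ``noise_frac`` (unit mean).

    Returns
    -------
    (FluorescenceExperiment, float)
        The experiment and the ground-truth EC50.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, 61.0, 10.0)
    control = spec.control_f0 * np.exp(-spec.control_decay * times)
    curves: dict[float, tuple[float, ...]] = {}
    for dose in spec.doses:
        caa = median_effect_caa(dose, spec.ec50, spec.slope)
        sample = control * (1.0 - caa / 100.0)
        if spec.noise_frac > 0:
            sigma = spec.noise_frac
            factors = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=times.shape))
            sample = sample * factors
        curves[float(dose)] = tuple(float(v) for v in sample)
    exp = FluorescenceExperiment(
        times=tuple(float(t) for t in times),
        control_curve=tuple(float(v) for v in control),
        sample_curves=curves,
    )
    return exp, spec.ec50
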