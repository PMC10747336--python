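"""Synthetic data generators for every pipeline stage.

No raw chromatograms, design responses, or plasma feature lists are publicly
deposited for this kind of study, so each stage is exercised on synthetic
inputs carrying the statistical structure the stage assumes:

* multi-origin herb fingerprints -- per-origin archetype area profiles with
  multiplicative lognormal batch noise, Gaussian retention-time jitter and
  Bernoulli peak dropout (defaults emulate 15 batches from 3 origins with 11
  shared peaks, the scale of a typical herb fingerprint study);
* Box-Behnken responses from a known quadratic surface plus Gaussian noise;
* LC-MS feature lists at the theoretical m/z of parent x biotransformation
  ions, perturbed by Gaussian ppm noise, with ground-truth labels.

Each generator owns an independent seed (the pipeline threads one global
seed through), so the modules stay decoupled; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .fingerprint import PeakTable
from .msid import (
    STANDARD_RULES,
    Feature,
    Formula,
    IonSpec,
    ModificationRule,
    ion_mz,
    normalize_adduct,
    parse_formula,
)
from .rsm import BBDesign, model_matrix


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic multi-origin fingerprint generator."""

    seed: int = 0
    n_origins: int = 3
    batches_per_origin: int = 5
    n_peaks: int = 11
    rt_jitter_sd: float = 0.01   # minutes; well inside the 0.1 min window
    area_noise_cv: float = 0.05  # batch-to-batch coefficient of variation
    dropout_prob: float = 0.0

    def __post_init__(self):
        if self.n_origins < 1 or self.batches_per_origin < 1 or self.n_peaks < 1:
            raise ParameterError("counts must be positive")
        if not 0 <= self.dropout_prob < 1:
            raise ParameterError("dropout_prob must be in [0, 1)")
        if self.rt_jitter_sd < 0 or self.area_noise_cv < 0:
            raise ParameterError("noise parameters must be non-negative")


#: consensus peak grid: peaks 2 min apart starting at 5 min, far beyond the
#: 0.1 min matching window so alignment is unambiguous at low jitter.
_RT_SPACING = 2.0
_RT_START = 5.0


def make_fingerprints(
    cfg: SynthConfig,
    origin_amplitudes: list[float] | None = None,
) -> tuple[list[PeakTable], list[str]]:
    """Generate batch peak tables with origin-level area structure.

    Each origin gets an archetype area vector (lognormal around 1000 area
    units, scaled by its amplitude); every batch is archetype x lognormal
    noise at the configured CV, with RT jitter and peak dropout.  Returns the
    peak tables and the ground-truth origin label of each batch.
    """
    rng = np.random.default_rng(cfg.seed)
    if origin_amplitudes is None:
        origin_amplitudes = [1.0] * cfg.n_origins
    if len(origin_amplitudes) != cfg.n_origins:
        raise ParameterError("origin_amplitudes length must equal n_origins")

    grid = _RT_START + _RT_SPACING * np.arange(cfg.n_peaks)
    # lognormal CV -> sigma of the underlying normal
    sigma = float(np.sqrt(np.log1p(cfg.area_noise_cv**2)))

    tables: list[PeakTable] = []
    labels: list[str] = []
    for o in range(cfg.n_origins):
        archetype = origin_amplitudes[o] * rng.lognormal(
            mean=np.log(1000.0), sigma=0.6, size=cfg.n_peaks
        )
        for b in range(cfg.batches_per_origin):
            area = archetype * rng.lognormal(mean=0.0, sigma=sigma, size=cfg.n_peaks)
            rt = grid + rng.normal(0.0, cfg.rt_jitter_sd, size=cfg.n_peaks)
            keep = rng.uniform(size=cfg.n_peaks) >= cfg.dropout_prob
            if not keep.any():  # a batch must keep at least one peak
                keep[rng.integers(cfg.n_peaks)] = True
            sid = f"O{o + 1}-B{b + 1}"
            tables.append(PeakTable(sid, rt[keep], area[keep]))
            labels.append(f"origin{o + 1}")
    return tables, labels


@dataclass(frozen=True)
class TrueSurface:
    """Generating quadratic surface OD_true(x) for coded x in [-1, 1]^3."""

    beta0: float
    linear: tuple[float, float, float]
    interaction: tuple[float, float, float]  # b12, b13, b23
    quadratic: tuple[float, float, float]
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, *self.linear, *self.interaction, *self.quadratic])

    def evaluate(self, coded) -> np.ndarray:
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        return model_matrix(coded) @ self.beta

    @classmethod
    def reference(cls, noise_sd: float = 0.0) -> "TrueSurface":
        """The decoction-extraction desirability surface used as the default
        generating model (the fitted coefficients of the 17-run study)."""
        return cls(
            beta0=0.8612,
            linear=(0.3228, 0.1158, 0.1248),
            interaction=(-0.1440, -0.1435, -0.0205),
            quadratic=(-0.2179, -0.0159, -0.0058),
            noise_sd=noise_sd,
        )


def make_bbd_responses(surface: TrueSurface, design: BBDesign, seed: int = 0) -> np.ndarray:
    """Responses y_i = OD_true(x_i) + N(0, noise_sd) at the design points."""
    levels = set(np.unique(design.runs))
    if not levels <= {-1.0, 0.0, 1.0}:
        raise ParameterError("design must have coded levels in {-1, 0, +1}")
    rng = np.random.default_rng(seed)
    y = surface.evaluate(design.runs)
    return y + rng.normal(0.0, surface.noise_sd, size=len(y))


#: Default parents for the synthetic plasma-feature generator: compounds from
#: the decoction with well-separated monoisotopic masses, so the candidate
#: ion set is unambiguous at the default annotation tolerance.
DEFAULT_FEATURE_PARENTS: dict[str, str] = {
    "stachydrine": "C7H13NO2",
    "apigenin": "C15H10O5",
    "chlorogenic acid": "C16H18O9",
    "akebia saponin B": "C40H64O12",
}

#: Phase-II rules used by default.  Demethylation is deliberately excluded:
#: combined with hydroxylation it maps one parent onto another flavonoid's
#: formula, which makes the "true" label genuinely ambiguous.
DEFAULT_FEATURE_RULES: tuple[str, ...] = (
    "glucuronidation",
    "sulfation",
    "hydroxylation",
)

DEFAULT_FEATURE_ADDUCTS: tuple[str, ...] = ("[M+H]+", "[M-H]-")


def make_feature_set(
    parents: dict[str, Formula | str] | None = None,
    rules: list[ModificationRule] | None = None,
    max_depth: int = 2,
    ppm_noise_sd: float = 2.0,
    seed: int = 0,
    n_features: int = 100,
    adducts: tuple[str, ...] = DEFAULT_FEATURE_ADDUCTS,
) -> tuple[list[Feature], list[tuple[str, tuple[str, ...], str]]]:
    """Generate LC-MS features at theoretical parent x modification m/z.

    Each feature is a uniformly drawn (parent, modification multiset of size
    0..max_depth, adduct) ion, with the measured m/z perturbed by Gaussian
    noise of ``ppm_noise_sd`` ppm.  Returns the features and the true
    (parent, modifications, adduct) labels.
    """
    if parents is None:
        parents = dict(DEFAULT_FEATURE_PARENTS)
    if not parents:
        raise ParameterError("parents must be non-empty")
    if max_depth < 1:
        raise ParameterError("max_depth must be >= 1")
    if rules is None:
        rules = [STANDARD_RULES[n] for n in DEFAULT_FEATURE_RULES]

    rng = np.random.default_rng(seed)
    parent_items = sorted(
        (name, f if isinstance(f, Formula) else parse_formula(f))
        for name, f in parents.items()
    )
    rules = sorted(rules, key=lambda r: r.name)

    features: list[Feature] = []
    labels: list[tuple[str, tuple[str, ...], str]] = []
    i = 0
    while len(features) < n_features:
        pname, pform = parent_items[rng.integers(len(parent_items))]
        depth = int(rng.integers(0, max_depth + 1))
        combo = tuple(sorted(rules[k].name for k in rng.integers(0, len(rules), depth)))
        f = pform
        for name in combo:
            f = f + STANDARD_RULES[name].delta
        if not f.is_valid_molecule():
            continue
        adduct = adducts[rng.integers(len(adducts))]
        mz = ion_mz(f, adduct)
        noisy = mz * (1.0 + rng.normal(0.0, ppm_noise_sd) * 1e-6)
        i += 1
        features.append(Feature(f"F{i}", noisy, IonSpec(normalize_adduct(adduct)).mode))
        labels.append((pname, combo, normalize_adduct(adduct)))
    return features, labels


def features_to_frame(features: list[Feature]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [f.id for f in features],
            "mz": [f.measured_mz for f in features],
            "ion_mode": [f.ion_mode for f in features],
        }
    )
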