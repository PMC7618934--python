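"""Synthetic cohort generation.

The study cohort this package analyses is an interview sample whose raw
data are not publicly deposited, so every pipeline stage is exercised on
synthetic cohorts with the same statistical skeleton: ~490 participants,
60 items on four scales, roughly 23% full-scale positives, a handful of
structurally silent (zero-variance) items, and a single latent risk trait
under a two-parameter logistic item-response model in which a subset of
"informative" items carries most of the discriminative signal.

Endorsement model: participant i draws a latent trait t_i ~ N(0, 1); item
j is endorsed with probability sigmoid(a_j * t_i - b_j) where a_j is the
discrimination (loading) and b_j a difficulty.  Informative items are
common and carry the discriminative signal (loading 2.0, endorsement
rates ~5-20%); "noise" items emulate the rarely endorsed residual items
of a real interview — endorsed by ~1% of participants, almost always the
most severe ones (high loading, high difficulty), so that an
informative-item short form misses only the occasional participant who
endorses nothing else, mirroring the false-negative pattern seen in
practice.  Default difficulties are derived from per-item target
endorsement rates; a shift applied to the informative difficulties is
calibrated by root-finding so the probability of endorsing at least one
item matches the target full-scale prevalence.  Severity and frequency
ratings are then sampled so that their dichotomization reproduces the
intended binary endorsement exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, special

from .instrument import (
    CohortDataset,
    Instrument,
    InstrumentError,
    ResponseRecord,
    dichotomize_cohort,
)


class CalibrationError(RuntimeError):
    """Raised when the prevalence target cannot be reached."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the study conditions: n=490, 23 informative items,
    6 silent items, ~23% CHR-P prevalence, ~2.5% psychosis-threshold
    cases, 80% female and 73% White participants.
    """

    n_participants: int = 490
    instrument: Optional[Instrument] = None
    n_informative_items: int = 23
    n_silent_items: int = 6
    latent_loading_informative: float = 2.0
    latent_loading_noise: float = 8.0
    item_threshold_offsets: Optional[dict[str, float]] = None
    target_chrp_prevalence: float = 0.23
    psychosis_rate: float = 0.025
    female_share: float = 0.80
    white_share: float = 0.73
    seed: int = 0

    def __post_init__(self) -> None:
        if self.instrument is None:
            self.instrument = Instrument.default()
        if self.n_informative_items + self.n_silent_items > len(self.instrument):
            raise InstrumentError(
                "n_informative_items + n_silent_items exceeds instrument size"
            )
        for name in ("target_chrp_prevalence", "psychosis_rate", "female_share", "white_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InstrumentError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.target_chrp_prevalence < 1.0:
            raise InstrumentError("target_chrp_prevalence must lie strictly in (0, 1)")
        if self.latent_loading_informative < 0 or self.latent_loading_noise < 0:
            raise InstrumentError("loadings must be non-negative")


def _partition_items(config: GeneratorConfig) -> tuple[list[str], list[str], list[str]]:
    """Deterministic silent/informative/noise item assignment.

    Silent items are drawn preferentially from the disorganized-speech
    scale (then one each from non-bizarre ideas and perceptual
    abnormalities), matching the empirical pattern that speech items are
    rarely endorsed.  Informative items are spread round-robin over the
    three non-speech scales, where the discriminative signal concentrates.
    """
    instr = config.instrument
    by_scale: dict[str, list[str]] = {}
    for it in instr.items:
        by_scale.setdefault(it.scale, []).append(it.item_id)

    silent_priority = (
        list(reversed(by_scale.get("disorganized_speech", [])))[:4]
        + list(reversed(by_scale.get("non_bizarre_ideas", [])))[:1]
        + list(reversed(by_scale.get("perceptual_abnormalities", [])))[:1]
        + [it.item_id for it in instr.items]  # fallback for unusual layouts
    )
    silent: list[str] = []
    for iid in silent_priority:
        if len(silent) == config.n_silent_items:
            break
        if iid not in silent:
            silent.append(iid)

    pool_scales = [
        "non_bizarre_ideas",
        "unusual_thought_content",
        "perceptual_abnormalities",
        "disorganized_speech",
    ]
    queues = {s: [i for i in by_scale.get(s, []) if i not in silent] for s in pool_scales}
    informative: list[str] = []
    while len(informative) < config.n_informative_items:
        progressed = False
        for s in pool_scales:
            if queues[s] and len(informative) < config.n_informative_items:
                informative.append(queues[s].pop(0))
                progressed = True
        if not progressed:  # pragma: no cover - guarded by config invariant
            raise InstrumentError("not enough items for requested informative count")
    noise = [i for i in instr.item_ids if i not in silent and i not in informative]
    return silent, informative, noise


#: target marginal endorsement rates spanned by the default difficulties
INFORMATIVE_RATE_RANGE = (0.20, 0.05)
NOISE_RATE_RANGE = (0.012, 0.007)


def _gauss_hermite_nodes(n: int = 81) -> tuple[np.ndarray, np.ndarray]:
    h, w = np.polynomial.hermite_e.hermegauss(n)  # weights for exp(-x^2/2)
    return h, w / np.sqrt(2 * np.pi)


def _offset_for_rate(loading: float, rate: float) -> float:
    """Difficulty b with marginal endorsement rate E_t[sigmoid(a*t - b)] = rate."""
    nodes, weights = _gauss_hermite_nodes()

    def f(b: float) -> float:
        return float(np.dot(weights, special.expit(loading * nodes - b))) - rate

    return float(optimize.brentq(f, -60.0, 60.0, xtol=1e-12))


def _default_offsets(
    config: GeneratorConfig, informative: list[str], noise: list[str]
) -> dict[str, float]:
    offsets = {}
    for ids, loading, (r_hi, r_lo) in (
        (informative, config.latent_loading_informative, INFORMATIVE_RATE_RANGE),
        (noise, config.latent_loading_noise, NOISE_RATE_RANGE),
    ):
        rates = np.linspace(r_hi, r_lo, len(ids)) if ids else []
        for iid, r in zip(ids, rates):
            offsets[iid] = _offset_for_rate(loading, float(r))
    return offsets


def calibrate_threshold_shift(
    loadings: np.ndarray,
    offsets: np.ndarray,
    target: float,
    adjustable: Optional[np.ndarray] = None,
) -> float:
    """Difficulty shift c on the adjustable items so P(endorse >= 1 item)
    equals ``target``.

    Integrates the any-item endorsement probability over the standard
    normal trait with Gauss-Hermite quadrature and solves for c by
    Brent's method.  By default the shift applies to every item; the
    generator passes a mask selecting the informative items so the noise
    items keep their absolute (rare) endorsement rates.
    """
    nodes, weights = _gauss_hermite_nodes()
    if adjustable is None:
        adjustable = np.ones(loadings.size, dtype=bool)
    if not adjustable.any():
        raise CalibrationError("no adjustable items to calibrate the prevalence with")

    def any_prob(c: float) -> float:
        # log P(no endorsement | t) summed over items, per quadrature node
        logits = np.outer(nodes, loadings) - offsets[None, :] - c * adjustable[None, :]
        log_none = np.sum(special.log_expit(-logits), axis=1)
        return float(1.0 - np.dot(weights, np.exp(log_none)))

    lo, hi = -40.0, 40.0
    if not (any_prob(hi) - target) * (any_prob(lo) - target) < 0:
        raise CalibrationError(
            f"prevalence target {target} unreachable with the given loadings/offsets"
        )
    return float(optimize.brentq(lambda c: any_prob(c) - target, lo, hi, xtol=1e-12))


def generate_cohort(config: GeneratorConfig) -> CohortDataset:
    """Generate a seeded synthetic cohort; identical config => identical cohort.

    The returned dataset is already scored (binary matrix and risk labels
    populated) and carries generator ground truth in ``provenance``:
    informative/noise/silent item ids, the calibrated difficulty shift,
    and each participant's latent trait.
    """
    return _generate(config, subgroup_shift=0.0)


def generate_bias_scenario(
    config: GeneratorConfig,
    subgroup_shift: float,
    group_field: str = "ethnicity_white",
    shifted_value=False,
) -> CohortDataset:
    """As :func:`generate_cohort`, but one demographic stratum's latent
    trait mean is shifted by ``subgroup_shift`` — a known prevalence
    difference for exercising the fairness audit."""
    return _generate(
        config,
        subgroup_shift=subgroup_shift,
        group_field=group_field,
        shifted_value=shifted_value,
    )


def _generate(
    config: GeneratorConfig,
    subgroup_shift: float,
    group_field: str = "ethnicity_white",
    shifted_value=False,
) -> CohortDataset:
    instr = config.instrument
    silent, informative, noise = _partition_items(config)
    offsets_map = dict(
        config.item_threshold_offsets or _default_offsets(config, informative, noise)
    )

    active = informative + noise
    loadings = np.array(
        [config.latent_loading_informative] * len(informative)
        + [config.latent_loading_noise] * len(noise)
    )
    offsets = np.array([offsets_map.get(iid, 0.0) for iid in active])
    adjustable = np.array([iid in informative for iid in active])
    shift = calibrate_threshold_shift(
        loadings, offsets, config.target_chrp_prevalence, adjustable=adjustable
    )

    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    # demographics first so a bias scenario with shift 0 is bit-identical
    sex = np.where(rng.random(n) < config.female_share, "female", "male")
    white = rng.random(n) < config.white_share
    age = np.clip(rng.normal(23.8, 5.0, n), 12.0, 35.0)

    trait = rng.standard_normal(n)
    if subgroup_shift != 0.0:
        if group_field == "sex":
            stratum = sex == shifted_value
        elif group_field == "ethnicity_white":
            stratum = white == bool(shifted_value)
        else:
            raise InstrumentError(f"unknown group_field {group_field!r}")
        trait = trait + subgroup_shift * stratum

    probs = special.expit(
        trait[:, None] * loadings[None, :]
        - offsets[None, :]
        - shift * adjustable[None, :]
    )
    endorsed = rng.random((n, len(active))) < probs

    psychosis_flag = rng.random(n) < config.psychosis_rate
    psych_item_idx = rng.integers(0, len(active), size=n)

    severity = np.zeros((n, len(instr)), dtype=int)
    frequency = np.zeros((n, len(instr)), dtype=int)
    col_of = {iid: j for j, iid in enumerate(instr.item_ids)}

    # severities consistent with the binary endorsement and graded in the
    # trait, so total severity separates predicted classes realistically
    p_sub = special.expit(0.8 * trait - 1.0)  # sub-threshold severity propensity
    p_pos = special.expit(trait)
    for k, iid in enumerate(active):
        j = col_of[iid]
        it = instr[iid]
        lo, hi = it.severity_positive_range
        pos = endorsed[:, k]
        sev_pos = lo + rng.binomial(hi - lo, p_pos)
        freq_pos = rng.integers(it.frequency_min, 7, size=n)
        sev_neg = rng.binomial(max(lo - 1, 0), p_sub)
        freq_neg = rng.integers(0, 7, size=n)
        severity[:, j] = np.where(pos, sev_pos, sev_neg)
        frequency[:, j] = np.where(pos, freq_pos, freq_neg)

    for i in np.nonzero(psychosis_flag)[0]:
        iid = active[psych_item_idx[i]]
        it = instr[iid]
        if it.psychosis_severity_min is None:
            continue
        j = col_of[iid]
        severity[i, j] = it.psychosis_severity_min
        frequency[i, j] = max(frequency[i, j], it.frequency_min)

    records = []
    width = len(str(n))
    for i in range(n):
        records.append(
            ResponseRecord(
                participant_id=f"p{i + 1:0{width}d}",
                severity={iid: int(severity[i, col_of[iid]]) for iid in instr.item_ids},
                frequency={iid: int(frequency[i, col_of[iid]]) for iid in instr.item_ids},
                sex=str(sex[i]),
                ethnicity_white=bool(white[i]),
                age_years=float(round(age[i], 1)),
            )
        )
    dataset = CohortDataset(instrument=instr, records=records)
    dataset.provenance = {
        "generator": "shortform.simulate",
        "seed": config.seed,
        "informative_items": informative,
        "noise_items": noise,
        "silent_items": silent,
        "threshold_shift": shift,
        "subgroup_shift": subgroup_shift,
        "latent_trait": trait.tolist(),
    }
    return dichotomize_cohort(dataset)
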