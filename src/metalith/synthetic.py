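"""Design-structured synthetic data with known ground truth.

Emulates the statistical structure of a quantified GC-TOF metabolite table
from a 2 genotypes x 2 treatments x 2 tissues mouse study:

* group sizes default to the study design (plasma WT/SCA1 control 11/16,
  lithium 12/18; cerebellum control 10/16, lithium 11/18);
* 416 detected metabolites of which 130 are identified against standards;
* log-normal within-group intensities — each metabolite has one baseline
  log-intensity plus additive log effects for the groups it is planted in,
  with per-metabolite noise sigma drawn from [0.1, 0.5];
* intensity-dependent missingness: detection probability is a logistic
  function of the latent log intensity (left-censoring-like, the mechanism
  the 50%-presence rule is designed for);
* a planted 10-fold treatment effect on one identified cerebellar compound
  in wild-type animals (emulating the ascorbate response) and a 0.5-fold
  genotype effect on another (emulating glucose-6-phosphate).

All randomness flows from a single integer seed through fixed-purpose
child streams, so each output is reproducible independent of call order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .netmap import DEFAULT_FP_LENGTH, Fingerprint, tanimoto
from .study_io import IntensityMatrix, ReactionPairTable

__all__ = [
    "TABLE1_GROUP_SIZES",
    "DropoutModel",
    "PlantedEffect",
    "SyntheticTruth",
    "SyntheticError",
    "default_truth",
    "generate_study",
    "generate_compounds",
    "generate_rpairs",
]


class SyntheticError(Exception):
    pass


# (tissue, genotype, treatment) -> number of animals
TABLE1_GROUP_SIZES: dict[tuple[str, str, str], int] = {
    ("plasma", "WT", "control"): 11,
    ("plasma", "SCA1", "control"): 16,
    ("plasma", "WT", "lithium"): 12,
    ("plasma", "SCA1", "lithium"): 18,
    ("cerebellum", "WT", "control"): 10,
    ("cerebellum", "SCA1", "control"): 16,
    ("cerebellum", "WT", "lithium"): 11,
    ("cerebellum", "SCA1", "lithium"): 18,
}


@dataclass(frozen=True)
class DropoutModel:
    """Logistic detection model on the latent natural-log intensity.

    P(detected) = expit(slope * (log_value - midpoint)): values one log unit
    below the midpoint are detected ~18% of the time at the default slope.
    """

    midpoint: float = 7.0
    slope: float = 1.5

    def detection_probability(self, log_value: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(self.slope * (np.asarray(log_value) - self.midpoint))


@dataclass(frozen=True)
class PlantedEffect:
    """Multiply the mean of one metabolite by ``fold_change`` for every
    sample matching all factor=level conditions in ``where``."""

    metabolite_id: str
    where: tuple  # ((factor, level), ...)
    fold_change: float

    @classmethod
    def make(cls, metabolite_id: str, where: Mapping[str, str], fold_change: float):
        if fold_change <= 0:
            raise SyntheticError("fold_change must be positive")
        return cls(metabolite_id, tuple(sorted(where.items())), float(fold_change))


@dataclass
class SyntheticTruth:
    """Everything the generator needs, and tests assert against."""

    group_sizes: dict = field(default_factory=lambda: dict(TABLE1_GROUP_SIZES))
    n_metabolites: int = 416
    n_identified: int = 130
    effects: tuple = ()
    sigma_range: tuple[float, float] = (0.1, 0.5)
    baseline_mean: float = 10.0  # natural-log intensity
    baseline_sd: float = 1.5
    dropout: DropoutModel | None = DropoutModel()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_identified > self.n_metabolites:
            raise SyntheticError("n_identified cannot exceed n_metabolites")
        for n in self.group_sizes.values():
            if n < 1:
                raise SyntheticError("group sizes must be positive")


def default_truth(seed: int = 0) -> SyntheticTruth:
    """The default study conditions.

    Besides the two designated effects (a 10-fold wild-type-only cerebellar
    treatment response and a 0.5-fold genotype effect), a broader panel of
    moderate effects emulates the study's signature: a shared cerebellar
    lithium response across both genotypes (mostly mild increases, the
    energy/purine/amino-acid pattern), a set of mostly-decreased cerebellar
    genotype effects, and a small plasma panel — so that multivariate class
    separation has a realistic signal to find.
    """
    cereb_li = {"tissue": "cerebellum", "treatment": "lithium"}
    cereb_sca = {"tissue": "cerebellum", "genotype": "SCA1"}
    plasma_li = {"tissue": "plasma", "treatment": "lithium"}
    effects = [
        # 10-fold treatment response in wild-type cerebellum (ascorbate-like)
        PlantedEffect.make(
            "M0001",
            {"tissue": "cerebellum", "genotype": "WT", "treatment": "lithium"},
            10.0,
        ),
        # 0.5-fold genotype effect in cerebellum (glucose-6-phosphate-like)
        PlantedEffect.make("M0002", cereb_sca, 0.5),
    ]
    # shared cerebellar lithium response, both genotypes (cf. the published
    # range of Li/control ratios, 0.5-4.3)
    li_fcs = [4.0, 2.7, 2.2, 1.8, 1.6, 1.5, 1.4, 1.4, 1.3, 1.3,
              1.2, 1.2, 1.2, 0.8, 0.8, 0.7, 0.5]
    for i, fc in enumerate(li_fcs):
        effects.append(PlantedEffect.make(f"M{5 + i:04d}", cereb_li, fc))
    # cerebellar genotype effects, mostly decreases
    geno_fcs = [0.6, 0.6, 0.7, 0.7, 0.7, 0.8, 0.8, 0.8, 1.2, 1.2]
    for i, fc in enumerate(geno_fcs):
        effects.append(PlantedEffect.make(f"M{25 + i:04d}", cereb_sca, fc))
    # mild plasma lithium panel
    for i, fc in enumerate([1.8, 1.5, 1.4, 1.3, 0.7]):
        effects.append(PlantedEffect.make(f"M{40 + i:04d}", plasma_li, fc))
    return SyntheticTruth(effects=tuple(effects), seed=seed)


def _rng(seed: int, purpose: int) -> np.random.Generator:
    # fixed-purpose child streams: reproducible independent of call order
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(purpose,)))


_PURPOSE_SAMPLES = 1
_PURPOSE_BASELINES = 2
_PURPOSE_NOISE = 3
_PURPOSE_DROPOUT = 4
_PURPOSE_COMPOUNDS = 5
_PURPOSE_RPAIRS = 6


def _metabolite_ids(n: int) -> list[str]:
    return [f"M{i + 1:04d}" for i in range(n)]


def _build_samples(truth: SyntheticTruth) -> pd.DataFrame:
    rng = _rng(truth.seed, _PURPOSE_SAMPLES)
    rows = []
    counter = itertools.count(1)
    for (tissue, genotype, treatment), n in sorted(truth.group_sizes.items()):
        for j in range(n):
            rows.append(
                {
                    "sample_id": f"S{next(counter):03d}",
                    "tissue": tissue,
                    "genotype": genotype,
                    "treatment": treatment,
                    "sex": "F" if j % 2 == 0 else "M",
                    "age": float(rng.uniform(13.0, 15.0)),  # weeks at sacrifice
                    "weight": float(np.clip(rng.normal(25.0, 3.0), 12.0, None)),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_study(truth: SyntheticTruth) -> tuple[IntensityMatrix, dict]:
    """Draw one synthetic intensity table under ``truth``.

    Returns the matrix and a truth record holding the planted parameters
    plus bookkeeping computed from the realized draw: per-metabolite sigma
    and baseline, and per-design-group detection fractions (for checking the
    presence filter against the generator).
    """
    samples = _build_samples(truth)
    n_samp = len(samples)
    mids = _metabolite_ids(truth.n_metabolites)
    mid_index = {m: i for i, m in enumerate(mids)}

    rng_b = _rng(truth.seed, _PURPOSE_BASELINES)
    baselines = rng_b.normal(truth.baseline_mean, truth.baseline_sd,
                             truth.n_metabolites)
    sigmas = rng_b.uniform(*truth.sigma_range, truth.n_metabolites)
    # effect-carrying compounds sit at the typical abundance: a differential
    # compound that happened to dominate the summed known-metabolite signal
    # would distort mTIC normalization for every other metabolite, which is
    # not the situation the planted effects emulate
    for eff in truth.effects:
        if eff.metabolite_id in mid_index:
            baselines[mid_index[eff.metabolite_id]] = truth.baseline_mean

    # additive log effects per (sample, metabolite)
    log_mu = np.tile(baselines, (n_samp, 1))
    for eff in truth.effects:
        if eff.metabolite_id not in mid_index:
            raise SyntheticError(f"effect references unknown metabolite "
                                 f"{eff.metabolite_id!r}")
        mask = pd.Series(True, index=samples.index)
        for factor, level in eff.where:
            if factor not in samples.columns:
                raise SyntheticError(f"effect references unknown factor {factor!r}")
            mask &= samples[factor] == level
        log_mu[mask.to_numpy(), mid_index[eff.metabolite_id]] += math.log(
            eff.fold_change
        )

    rng_n = _rng(truth.seed, _PURPOSE_NOISE)
    log_values = log_mu + rng_n.normal(0.0, 1.0, log_mu.shape) * sigmas

    detected = np.ones(log_values.shape, dtype=bool)
    if truth.dropout is not None:
        rng_d = _rng(truth.seed, _PURPOSE_DROPOUT)
        p_det = truth.dropout.detection_probability(log_values)
        detected = rng_d.random(log_values.shape) < p_det

    values = np.exp(log_values)
    values[~detected] = np.nan
    values_df = pd.DataFrame(values, index=samples.index, columns=mids)

    annotations = pd.DataFrame(
        {
            "name": [f"compound_{m}" for m in mids],
            "identified": [i < truth.n_identified for i in range(len(mids))],
            "kegg": [
                f"C{i + 1:05d}" if i < truth.n_identified else ""
                for i in range(len(mids))
            ],
        },
        index=pd.Index(mids, name="metabolite_id"),
    )

    matrix = IntensityMatrix(values=values_df, samples=samples,
                             annotations=annotations)

    # realized per-group detection fractions, for filter cross-checks
    det_frac: dict[tuple, np.ndarray] = {}
    for key in sorted(truth.group_sizes):
        sids = samples.index[
            (samples["tissue"] == key[0])
            & (samples["genotype"] == key[1])
            & (samples["treatment"] == key[2])
        ]
        det_frac[key] = values_df.loc[sids].notna().mean(axis=0).to_numpy()

    record = {
        "truth": truth,
        "metabolite_ids": mids,
        "baselines": baselines,
        "sigmas": sigmas,
        "detection_fraction": det_frac,
    }
    return matrix, record


def truth_sidecar(record: dict) -> pd.DataFrame:
    """Flatten a truth record into a per-metabolite TSV-ready frame."""
    truth: SyntheticTruth = record["truth"]
    mids = record["metabolite_ids"]
    effects = {m: [] for m in mids}
    for eff in truth.effects:
        where = ";".join(f"{f}={v}" for f, v in eff.where)
        effects[eff.metabolite_id].append(f"{where}:{eff.fold_change:g}")
    return pd.DataFrame(
        {
            "baseline_log": record["baselines"],
            "sigma": record["sigmas"],
            "effects": ["|".join(effects[m]) for m in mids],
        },
        index=pd.Index(mids, name="metabolite_id"),
    )


# ---------------------------------------------------------------------------
# compounds (fingerprints) and reactant pairs


def generate_compounds(
    n: int,
    fp_length: int = DEFAULT_FP_LENGTH,
    n_clusters: int = 4,
    seed: int = 0,
    core_bits: int = 60,
    noise_bits: int = 12,
) -> tuple[dict[str, Fingerprint], dict[str, int]]:
    """Clustered binary fingerprints with known structure classes.

    Each cluster shares a disjoint block of ``core_bits`` set bits; each
    member adds ``noise_bits`` random extra bits. Expected within-cluster
    Tanimoto is core/(core + 2*noise) (> 0.5 at the defaults) and
    between-cluster similarity is near 0; both are asserted at generation
    time so a miscalibrated draw fails loudly rather than silently skewing
    downstream tests.
    """
    if n < 2:
        raise SyntheticError("need n >= 2 compounds")
    if n_clusters > n:
        raise SyntheticError("more clusters than compounds")
    if n_clusters * core_bits + noise_bits * 4 > fp_length:
        raise SyntheticError("fingerprint too short for the requested clusters")
    rng = _rng(seed, _PURPOSE_COMPOUNDS)
    ids = _metabolite_ids(n)
    labels = {mid: i % n_clusters for i, mid in enumerate(ids)}
    core_slots = {
        c: range(c * core_bits, (c + 1) * core_bits) for c in range(n_clusters)
    }
    noise_pool = np.arange(n_clusters * core_bits, fp_length)
    fps: dict[str, Fingerprint] = {}
    for mid in ids:
        bits = np.zeros(fp_length, dtype=int)
        bits[list(core_slots[labels[mid]])] = 1
        bits[rng.choice(noise_pool, size=noise_bits, replace=False)] = 1
        fps[mid] = Fingerprint.from_bits(bits)

    # calibration assertions on the realized draw
    within, between = [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            s = tanimoto(fps[a], fps[b])
            (within if labels[a] == labels[b] else between).append(s)
    if within and np.mean(within) <= 0.5:
        raise SyntheticError(
            f"within-cluster similarity calibration failed: {np.mean(within):.3f}"
        )
    if between and np.mean(between) >= 0.3:
        raise SyntheticError(
            f"between-cluster similarity calibration failed: {np.mean(between):.3f}"
        )
    return fps, labels


def generate_rpairs(
    ids: Sequence[str],
    k: int,
    seed: int = 0,
    n_distractors: int = 3,
    id_to_ref=None,
) -> tuple[ReactionPairTable, list[tuple[str, str]]]:
    """Reactant-pair table with exactly ``k`` resolvable main pairs among
    ``ids`` plus distractor lines referencing absent compounds.

    ``id_to_ref`` optionally maps study ids to external compound references
    (default: identity). Returns the table and the planted id pairs.
    """
    ids = list(ids)
    max_pairs = len(ids) * (len(ids) - 1) // 2
    if k > max_pairs:
        raise SyntheticError(f"k={k} exceeds the {max_pairs} possible pairs")
    if id_to_ref is None:
        id_to_ref = {i: i for i in ids}
    rng = _rng(seed, _PURPOSE_RPAIRS)
    all_pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    chosen_idx = rng.choice(len(all_pairs), size=k, replace=False) if k else []
    planted = [all_pairs[i] for i in sorted(chosen_idx)]
    rows: list[tuple[str, str, str]] = []
    for a, b in planted:
        ra, rb = id_to_ref[a], id_to_ref[b]
        key = (ra, rb) if ra <= rb else (rb, ra)
        rows.append((key[0], key[1], "main"))
    for d in range(n_distractors):
        rows.append((f"X_absent_{d:02d}", f"X_absent_{d + 1:02d}", "main"))
        rows.append((f"X_cofac_{d:02d}", f"X_cofac_{d + 1:02d}", "cofac"))
    return ReactionPairTable(pairs=rows), planted
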