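"""Synthetic qPCR plates and miRNA-seq counts with known ground truth.

The generator emulates the statistical structure the analysis assumes:
~750 assayed miRNAs, four groups of three replicates, group-specific
detection probabilities, Gaussian within-group Ct noise truncated to the
quantifiable window, a fraction of wells failing QC metrics, occasional
blanked replicates (so imputation has work to do), injected ΔCt group
effects for differential-expression recovery, and negative-binomial
sequencing counts tied to the same latent abundances as the plate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CountMatrix, GroupDesign, SyntheticTruth, WellRecord

__all__ = ["SimConfig", "generate_plate", "generate_counts", "design_from_config"]

#: Default per-group detection probabilities, mimicking observed
#: qPCR-array detection rates in neuronal cells (on the order of
#: 150-230 of ~750 assays per cell type, with the human neuroblastoma
#: line detecting the most).
DEFAULT_DETECT_PROB = {
    "neuron": 0.21,
    "HT22": 0.20,
    "N2A": 0.24,
    "SHSY5Y": 0.30,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the reference design: 750 assays, 4 cell types with
    3 replicates each, 0.5-cycle replicate noise, baselines spread over
    the usable Ct range, and a 5% per-well QC failure rate.
    """

    n_mirna: int = 750
    groups: dict = field(
        default_factory=lambda: {"neuron": 3, "HT22": 3, "N2A": 3, "SHSY5Y": 3}
    )
    detect_prob: dict = field(default_factory=lambda: dict(DEFAULT_DETECT_PROB))
    detect_rho: float = 0.8
    baseline_ct_range: tuple[float, float] = (12.0, 34.0)
    sigma_ct: float = 0.5
    n_de: int = 0
    effect_ct: float = 2.0
    effect_group: str | None = None  # defaults to the second group
    qc_fail_prob: float = 0.05
    #: Opt-in: blank one extra replicate per detected pair at this rate
    #: to exercise the imputation path. QC failures already produce
    #: organic missingness; mean-imputed replicates deflate within-group
    #: variance, so heavy blanking inflates the DE false-discovery rate.
    missing_rep_prob: float = 0.0
    ct_low: float = 10.0
    ct_high: float = 35.0
    seq_detect_prob: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for g, p in self.detect_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"detect_prob[{g}] = {p} outside [0, 1]")
        if not 0.0 <= self.detect_rho <= 1.0:
            raise ValueError("detect_rho must lie in [0, 1]")
        for p in (self.qc_fail_prob, self.missing_rep_prob, self.seq_detect_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.sigma_ct < 0:
            raise ValueError("sigma_ct must be >= 0")
        if self.n_de > self.n_mirna:
            raise ValueError("n_de cannot exceed n_mirna")
        missing = [g for g in self.groups if g not in self.detect_prob]
        if missing:
            raise ValueError(f"groups without detection probability: {missing}")

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "baseline_ct_range" in d:
            d["baseline_ct_range"] = tuple(d["baseline_ct_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_ct_range"] = list(self.baseline_ct_range)
        return d


def design_from_config(config: SimConfig, control_group: str | None = None) -> GroupDesign:
    """The GroupDesign implied by a simulation config."""
    members = {
        g: [f"{g}_{i + 1}" for i in range(k)] for g, k in config.groups.items()
    }
    return GroupDesign(members, control_group=control_group)


def _latents(config: SimConfig, rng: np.random.Generator):
    """Latent quantities shared by the plate and count generators.

    Drawn first, in a fixed order, so both generators agree on baseline
    abundances for the same seed.
    """
    mirnas = [f"sim-miR-{i + 1:04d}" for i in range(config.n_mirna)]
    lo, hi = config.baseline_ct_range
    baseline = pd.Series(rng.uniform(lo, hi, size=config.n_mirna), index=mirnas)
    groups = config.group_names
    probs = pd.DataFrame(
        {g: np.full(config.n_mirna, config.detect_prob[g]) for g in groups},
        index=mirnas,
    )
    # Detection via a Gaussian copula: a shared per-miRNA propensity
    # induces positive cross-group association (miRNAs expressed in one
    # cell type tend to be expressed in the others, as in real data)
    # while each group keeps its exact marginal detection probability.
    # detect_rho = 0 recovers fully independent groups.
    from scipy.stats import norm as _norm

    rho = config.detect_rho
    z_shared = rng.standard_normal((config.n_mirna, 1))
    z_noise = rng.standard_normal((config.n_mirna, len(groups)))
    z = np.sqrt(rho) * z_shared + np.sqrt(1.0 - rho) * z_noise
    detected = pd.DataFrame(
        z < _norm.ppf(probs.to_numpy()),
        index=mirnas,
        columns=groups,
    )
    effect = pd.DataFrame(0.0, index=mirnas, columns=groups)
    de_mirnas: tuple[str, ...] = ()
    if config.n_de > 0:
        target = config.effect_group or (groups[1] if len(groups) > 1 else groups[0])
        # Only assays whose shifted mean stays well inside the Ct window
        # can carry the effect; otherwise truncation would clip the
        # injected shift and the recorded truth would not be realized.
        margin = abs(config.effect_ct) + 2.0 * config.sigma_ct
        eligible = np.flatnonzero(
            (baseline.to_numpy() - margin > config.ct_low)
            & (baseline.to_numpy() + margin < config.ct_high)
        )
        if len(eligible) < config.n_de:
            raise ValueError(
                f"only {len(eligible)} assays can carry a ±{config.effect_ct} "
                f"cycle shift inside the Ct window; reduce n_de"
            )
        idx = rng.choice(eligible, size=config.n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.n_de)
        de_mirnas = tuple(mirnas[i] for i in sorted(idx))
        for i, s in zip(idx, signs):
            effect.iloc[i, effect.columns.get_loc(target)] = s * config.effect_ct
    seq_present = pd.Series(
        rng.random(config.n_mirna) < config.seq_detect_prob, index=mirnas
    )
    return mirnas, baseline, probs, detected, effect, de_mirnas, seq_present


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sigma: float, lo: float, hi: float
) -> np.ndarray:
    """Normal(mean, sigma) truncated to (lo, hi), by rejection."""
    mean = np.asarray(mean, float)
    if sigma == 0:
        return np.clip(mean, lo + 1e-9, hi - 1e-9)
    out = rng.normal(mean, sigma)
    bad = (out <= lo) | (out >= hi)
    for _ in range(1000):
        if not bad.any():
            break
        out[bad] = rng.normal(mean[bad], sigma)
        bad = (out <= lo) | (out >= hi)
    return np.clip(out, lo + 1e-9, hi - 1e-9)


def generate_plate(config: SimConfig) -> tuple[list[WellRecord], SyntheticTruth]:
    """Simulate one full plate of well records plus its latent truth.

    Every (miRNA, sample) well gets a record: detected pairs produce
    truncated-normal Cts around ``baseline + effect``; undetected pairs
    report no Ct ("Undetermined"). A ``qc_fail_prob`` fraction of wells
    receive a failing amplification score or Cq confidence, and each
    detected pair may have one replicate blanked (missing Ct) with
    probability ``missing_rep_prob``. Identical seeds give identical
    record lists.
    """
    rng = np.random.default_rng(config.seed)
    mirnas, baseline, probs, detected, effect, de_mirnas, _seq = _latents(config, rng)
    design = design_from_config(config)
    groups = config.group_names
    records: list[WellRecord] = []
    n = config.n_mirna
    for g in groups:
        samples = design.members[g]
        k = len(samples)
        det_g = detected[g].to_numpy()
        mean_ct = baseline.to_numpy() + effect[g].to_numpy()
        cts = _truncated_normal(
            rng,
            np.repeat(mean_ct[:, None], k, axis=1),
            config.sigma_ct,
            config.ct_low,
            config.ct_high,
        )
        qc_fail = rng.random((n, k)) < config.qc_fail_prob
        fail_on_amp = rng.random((n, k)) < 0.5
        amp = rng.uniform(1.3, 2.0, size=(n, k))
        cq = rng.uniform(0.85, 1.0, size=(n, k))
        amp_bad = rng.uniform(0.5, 1.2, size=(n, k))
        cq_bad = rng.uniform(0.0, 0.75, size=(n, k))
        blank = rng.random(n) < config.missing_rep_prob
        blank_rep = rng.integers(0, k, size=n)
        for i, m in enumerate(mirnas):
            for j, s in enumerate(samples):
                if det_g[i]:
                    ct: float | None = float(cts[i, j])
                    if blank[i] and blank_rep[i] == j:
                        ct = None
                    a, c = float(amp[i, j]), float(cq[i, j])
                    if qc_fail[i, j]:
                        if fail_on_amp[i, j]:
                            a = float(amp_bad[i, j])
                        else:
                            c = float(cq_bad[i, j])
                else:
                    ct = None
                    a, c = float(amp_bad[i, j]), float(cq_bad[i, j])
                records.append(
                    WellRecord(
                        sample_id=s, group=g, mirna_id=m, ct=ct, amp_score=a, cq_conf=c
                    )
                )
    truth = SyntheticTruth(
        detect_prob=probs,
        baseline_ct=baseline,
        effect=effect,
        sigma_ct=config.sigma_ct,
        qc_fail_prob=config.qc_fail_prob,
        detected=detected,
        de_mirnas=de_mirnas,
    )
    return records, truth


def generate_counts(
    config: SimConfig,
    n_samples: int = 3,
    dispersion: float = 0.2,
    lib_size: float = 8e6,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate a negative-binomial miRNA-seq count matrix.

    Per-miRNA means derive from the same latent baseline Cts as the
    plate generator (abundance proportional to ``2^(35 − baseline Ct)``
    for seq-present miRNAs), so qPCR and sequencing profiles of one seed
    correlate by construction. Counts follow NB with variance
    ``mu + dispersion * mu^2``; seq-absent miRNAs get near-zero means so
    they fall below the count filter with high probability.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(config.seed)
    mirnas, baseline, probs, _detected, effect, _de, seq_present = _latents(config, rng)
    count_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7_919]).generate_state(1)[0]
    )
    expr = (35.0 - baseline.to_numpy()).clip(min=0)
    weights = np.where(seq_present.to_numpy(), 2.0 ** expr, 0.0)
    total = weights.sum()
    if total == 0:
        mu = np.full(config.n_mirna, 0.05)
    else:
        mu = lib_size * weights / total
        mu = np.where(seq_present.to_numpy(), np.maximum(mu, 1e-3), 0.05)
    nb_n = 1.0 / dispersion
    counts = np.empty((config.n_mirna, n_samples), dtype=np.int64)
    for j in range(n_samples):
        p = nb_n / (nb_n + mu)
        counts[:, j] = count_rng.negative_binomial(nb_n, p)
    samples = [f"seq_{j + 1}" for j in range(n_samples)]
    matrix = CountMatrix(pd.DataFrame(counts, index=mirnas, columns=samples))
    truth = SyntheticTruth(
        detect_prob=pd.DataFrame(
            {"seq": np.full(config.n_mirna, config.seq_detect_prob)}, index=mirnas
        ),
        baseline_ct=baseline,
        effect=effect,
        sigma_ct=config.sigma_ct,
        qc_fail_prob=0.0,
        detected=pd.DataFrame({"seq": seq_present}),
        de_mirnas=(),
    )
    return matrix, truth
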