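"""Synthetic two-group spectral-count data with known ground truth.

The generator emulates a two-group label-free shotgun-proteomics study of
the shape used for case/control synovial-tissue comparison: a few hundred
proteins, a small control group and a larger case group, triplicate
injections per biological sample.  The model is, per protein ``p`` and
biological sample ``j``:

    mu_pj = baseline_p * depth_j * fold_p^[j in case group]

with log-normal baselines (heavy-tailed protein abundance), log-normal
per-sample depth factors, a negative-binomial sample-level count
(variance mu + mu^2/dispersion; Poisson in the dispersion -> infinity
limit), a logistic extra-dropout that zeroes low-abundance observations,
and multinomial thinning of each sample count into technical-replicate
injections (so pooling replicates recovers the sample count exactly).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .count_data import CountMatrix, DesignColumn, GroupDesign, ProteinMeta
from .errors import ParameterError, ReconciliationError
from .stats import LABEL_CASE, LABEL_CONTROL, LABEL_NS, DiffExprRecord


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic count generator.

    Defaults mirror the target study shape: 508 proteins, 5 control vs 15
    case biological samples, 3 injections each, 20% of proteins carrying a
    group effect with fold changes 2 or 4 in either direction.
    ``abundance_log_mean``/``abundance_log_sd`` parameterize the log-normal
    baseline mean count per sample; ``depth_log_sd`` the per-sample
    library-size variation; ``dispersion`` the negative-binomial size
    (``math.inf`` gives Poisson counts); ``dropout_midpoint`` (expected
    count at which half the observations drop out) and ``dropout_slope``
    the logistic extra-dropout.
    """

    n_proteins: int = 508
    n_control: int = 5
    n_case: int = 15
    replicates: int = 3
    abundance_log_mean: float = math.log(5.0)
    abundance_log_sd: float = 1.5
    depth_log_sd: float = 0.3
    dispersion: float = 2.0
    de_fraction: float = 0.2
    fold_changes: tuple[float, ...] = (2.0, 4.0)
    dropout_midpoint: float = 1.0
    dropout_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_control, self.n_case, self.replicates) < 1:
            raise ParameterError("n_proteins, group sizes and replicates must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ParameterError("de_fraction must be in [0, 1]")
        if not self.dispersion > 0:
            raise ParameterError("dispersion must be > 0")
        if any(fc <= 0 for fc in self.fold_changes):
            raise ParameterError("fold changes must be > 0")
        if self.de_fraction > 0 and not self.fold_changes:
            raise ParameterError("fold_changes must be non-empty when de_fraction > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        if "fold_changes" in raw:
            raw["fold_changes"] = tuple(raw["fold_changes"])
        return cls(**raw)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``fold`` is the case/control mean ratio actually applied (1 for null
    proteins; below 1 for control-enriched effects); ``de_flag`` marks
    proteins with a group effect.
    """

    config: SimulationConfig
    entry_names: tuple[str, ...]
    baselines: tuple[float, ...]
    folds: tuple[float, ...]
    de_flags: tuple[bool, ...]

    @property
    def n_de(self) -> int:
        return sum(self.de_flags)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entry_name": self.entry_names,
                "baseline": self.baselines,
                "fold": self.folds,
                "de_flag": [int(f) for f in self.de_flags],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if math.isinf(dispersion):
        return rng.poisson(mu)
    # NB with mean mu and variance mu + mu^2/k
    return rng.negative_binomial(dispersion, dispersion / (dispersion + mu))


def generate_dataset(config: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one synthetic count matrix and its ground truth.

    Deterministic for a fixed config (including its seed).  Replicate
    counts are a multinomial split of each sample-level count, so pooling
    replicates reproduces the sample counts exactly.
    """
    rng = np.random.default_rng(config.seed)
    n_p = config.n_proteins
    n_samples = config.n_control + config.n_case
    width = max(4, len(str(n_p)))

    baselines = rng.lognormal(config.abundance_log_mean, config.abundance_log_sd, n_p)
    # mean-one depth factors
    depths = rng.lognormal(-config.depth_log_sd**2 / 2, config.depth_log_sd, n_samples)

    n_de = round(config.de_fraction * n_p)
    de_idx = rng.choice(n_p, size=n_de, replace=False)
    folds = np.ones(n_p)
    if n_de:
        fc = rng.choice(np.asarray(config.fold_changes, dtype=float), size=n_de)
        direction = rng.choice([1.0, -1.0], size=n_de)
        folds[de_idx] = fc**direction

    is_case = np.zeros(n_samples, dtype=bool)
    is_case[config.n_control :] = True
    mu = baselines[:, None] * depths[None, :]
    mu = mu * np.where(is_case[None, :], folds[:, None], 1.0)

    counts = _sample_counts(rng, mu, config.dispersion)
    # logistic extra-dropout at the sample level, driven by expected count
    p_drop = expit(-config.dropout_slope * (mu - config.dropout_midpoint))
    counts = np.where(rng.random(mu.shape) < p_drop, 0, counts)

    # multinomial thinning into technical replicates (totals conserved)
    rep_probs = np.full(config.replicates, 1.0 / config.replicates)
    rep_counts = rng.multinomial(counts.reshape(-1), rep_probs).reshape(
        n_p, n_samples, config.replicates
    )

    proteins = tuple(
        ProteinMeta(entry_name=f"P{i:0{width}d}", gene_id=f"G{i:0{width}d}")
        for i in range(1, n_p + 1)
    )
    columns = []
    for j in range(n_samples):
        group = "case" if is_case[j] else "control"
        sid = f"{'B' if is_case[j] else 'A'}{j + 1:03d}"
        for r in range(1, config.replicates + 1):
            columns.append(
                DesignColumn(column_id=f"{sid}_r{r}", sample_id=sid, replicate=r, group=group)
            )
    matrix = CountMatrix(
        proteins=proteins,
        design=GroupDesign(columns=tuple(columns), control_label="control"),
        counts=rep_counts.reshape(n_p, n_samples * config.replicates),
    )
    truth = SyntheticTruth(
        config=config,
        entry_names=tuple(p.entry_name for p in proteins),
        baselines=tuple(baselines),
        folds=tuple(folds),
        de_flags=tuple(bool(folds[i] != 1.0) for i in range(n_p)),
    )
    return matrix, truth


@dataclass(frozen=True)
class PerformanceSummary:
    """Operating characteristics of one analysed synthetic dataset."""

    n_null: int
    n_de: int
    type1_error: float | None
    power_by_fold: dict[float, float] = field(default_factory=dict)
    sign_accuracy_spi: float | None = None
    sign_accuracy_rsc: float | None = None
    fdr_by_label: dict[str, float | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "type1_error", "stratum": "null", "value": self.type1_error},
            {"metric": "sign_accuracy_spi", "stratum": "de", "value": self.sign_accuracy_spi},
            {"metric": "sign_accuracy_rsc", "stratum": "de", "value": self.sign_accuracy_rsc},
        ]
        for fold, power in sorted(self.power_by_fold.items()):
            rows.append({"metric": "power", "stratum": f"fold_{fold:g}", "value": power})
        for label, fdr in sorted(self.fdr_by_label.items()):
            rows.append({"metric": "empirical_fdr", "stratum": label, "value": fdr})
        return pd.DataFrame(rows, columns=["metric", "stratum", "value"])


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def evaluate_calls(
    records: Sequence[DiffExprRecord], truth: SyntheticTruth
) -> PerformanceSummary:
    """Compare classification calls against the generator's ground truth.

    A protein counts as *called* when its label is not ``not_significant``.
    Power is reported per fold-change magnitude (fold 4 pools the 4x-up
    and 4x-down proteins); sign accuracy asks whether SpI and R_SC point
    in the true direction on DE proteins; the empirical FDR of a label
    class is the fraction of its calls that are false (null protein or
    wrong direction).
    """
    if {r.entry_name for r in records} != set(truth.entry_names):
        raise ReconciliationError("records and truth cover different protein sets")
    fold_of = dict(zip(truth.entry_names, truth.folds))
    de_of = dict(zip(truth.entry_names, truth.de_flags))

    null_recs = [r for r in records if not de_of[r.entry_name]]
    de_recs = [r for r in records if de_of[r.entry_name]]
    called = lambda r: r.label != LABEL_NS

    type1 = _ratio(sum(called(r) for r in null_recs), len(null_recs))

    power_by_fold: dict[float, float] = {}
    for mag in sorted({max(f, 1 / f) for f in truth.folds if f != 1.0}):
        stratum = [
            r for r in de_recs if math.isclose(max(fold_of[r.entry_name], 1 / fold_of[r.entry_name]), mag)
        ]
        power_by_fold[mag] = _ratio(sum(called(r) for r in stratum), len(stratum))

    def sign_ok(value: float | None, fold: float) -> bool:
        if value is None:
            return False
        return (value > 0) == (fold > 1.0)

    de_scored = [r for r in de_recs if r.spi is not None]
    acc_spi = _ratio(
        sum(sign_ok(r.spi, fold_of[r.entry_name]) for r in de_scored), len(de_scored)
    )
    acc_rsc = _ratio(
        sum(sign_ok(r.rsc, fold_of[r.entry_name]) for r in de_scored), len(de_scored)
    )

    fdr_by_label: dict[str, float | None] = {}
    for label, want_up in ((LABEL_CASE, True), (LABEL_CONTROL, False)):
        calls = [r for r in records if r.label == label]
        false_calls = sum(
            not (de_of[r.entry_name] and (fold_of[r.entry_name] > 1.0) == want_up)
            for r in calls
        )
        fdr_by_label[label] = _ratio(false_calls, len(calls))

    return PerformanceSummary(
        n_null=len(null_recs),
        n_de=len(de_recs),
        type1_error=type1,
        power_by_fold=power_by_fold,
        sign_accuracy_spi=acc_spi,
        sign_accuracy_rsc=acc_rsc,
        fdr_by_label=fdr_by_label,
    )
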