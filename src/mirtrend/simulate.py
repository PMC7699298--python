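"""Seeded synthetic-data generators with known ground truth.

Every downstream stage of the package can be exercised without external data:
the generators here produce pooled small-RNA count tables, log2 expression
matrices with a two-factor (context x treatment) design, qPCR Ct tables and
per-study meta-analysis summaries, each together with the planted truth.

Count model: negative binomial parameterised by mean ``mu`` and dispersion
``alpha`` (variance ``mu + alpha * mu^2``), reducing to Poisson at
``alpha = 0``.  Expression model: additive Gaussian noise on the log2 scale,
matching the log-intensity convention of microarray data.

Randomness: one seed per generator config fans out to a per-generator child
stream via ``numpy.random.SeedSequence(seed, spawn_key=(stream_index,))``
with a fixed stream index per generator, so partial re-runs are reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pool import PoolCountTable
from .qpcr import CtTable
from .meta import StudySummary

__all__ = [
    "ConfigError",
    "PoolSimConfig",
    "TrendSimConfig",
    "MetaSimConfig",
    "simulate_pool_counts",
    "simulate_expression",
    "simulate_ct_table",
    "simulate_meta_studies",
]

# Fixed stream indices for seed fan-out; never reorder.
_STREAMS = {"pool": 0, "expression": 1, "ct": 2, "meta": 3}


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean mu; Poisson limit at dispersion 0."""
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# pooled count tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolSimConfig:
    """Pooled-sample miRNA-seq simulation.

    Defaults emulate a three-group (healthy / tumor / metastatic) pooled
    serum design sequenced in duplicate, with one planted down-trending
    miRNA whose per-group multiplicative effects (1, 0.64, 0.55) correspond
    to log2 fold changes of about -0.64 and -0.86 versus the healthy group;
    all other miRNAs are constant across groups.
    """

    n_mirnas: int = 200
    groups: tuple[str, ...] = ("healthy", "tumor", "metastatic")
    replicates_per_group: int = 2
    library_size: float = 5e6
    dispersion: float = 0.05
    planted: tuple[tuple[int, tuple[float, ...]], ...] = ((0, (1.0, 0.64, 0.55)),)
    seed: int = 0

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ConfigError("n_mirnas must be a positive integer")
        if len(self.groups) < 2 or len(set(self.groups)) != len(self.groups):
            raise ConfigError("groups must be >= 2 distinct labels")
        if self.replicates_per_group < 2:
            raise ConfigError("replicates_per_group must be >= 2")
        if not self.library_size > 0:
            raise ConfigError("library_size must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        for mid, effects in self.planted:
            if not 0 <= mid < self.n_mirnas:
                raise ConfigError(f"planted mirna_id {mid} outside [0, n_mirnas)")
            if len(effects) != len(self.groups):
                raise ConfigError(f"planted effects for mirna_id {mid} must have one value per group")
            if any(e <= 0 for e in effects):
                raise ConfigError(f"planted effects for mirna_id {mid} must be strictly positive")


def simulate_pool_counts(config: PoolSimConfig) -> tuple[PoolCountTable, dict]:
    """Simulate a pooled count table; returns (table, planted truth).

    The expected count of miRNA i in a sample of group g is
    ``library_size * share_i * effect_i(g)`` where ``share_i`` is the
    miRNA's baseline library-share (log-normal across miRNAs).
    """
    config.validate()
    rng = _child_rng(config.seed, "pool")
    shares = rng.lognormal(mean=0.0, sigma=2.0, size=config.n_mirnas)
    shares /= shares.sum()
    effects = np.ones((config.n_mirnas, len(config.groups)))
    for mid, eff in config.planted:
        effects[mid] = eff

    mirna_ids = [f"mir{i:04d}" for i in range(config.n_mirnas)]
    sample_ids, groups_of, cols = [], {}, []
    for gi, grp in enumerate(config.groups):
        mu = config.library_size * shares * effects[:, gi]
        for r in range(1, config.replicates_per_group + 1):
            sid = f"{grp}_{r}"
            sample_ids.append(sid)
            groups_of[sid] = grp
            cols.append(_nb_counts(rng, mu, config.dispersion))
    counts = pd.DataFrame(np.column_stack(cols), index=mirna_ids, columns=sample_ids)
    table = PoolCountTable(counts=counts, groups=pd.Series(groups_of))
    truth = {
        "planted": {mirna_ids[mid]: tuple(eff) for mid, eff in config.planted},
        "shares": pd.Series(shares, index=mirna_ids),
        "config": config,
    }
    return table, truth


# ---------------------------------------------------------------------------
# expression matrices with planted treatment trends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendSimConfig:
    """Two-context, three-treatment expression simulation.

    Treatments are ordered by increasing miRNA activity
    (inhibitor < control < mimic), measured in triplicate per cell.  A
    planted "promoted" gene gains ``effect`` log2 units per treatment step in
    each flagged context (both contexts when ``consistent`` is true, with the
    trend reversed in the second context otherwise); "inhibited" genes mirror
    this downward.  Null genes have constant mean.  ``noise_sd`` is the
    replicate-level Gaussian standard deviation in log2 units.
    """

    n_genes: int = 1000
    contexts: tuple[str, str] = ("monolayer", "csc")
    treatments: tuple[str, str, str] = ("inhibitor", "control", "mimic")
    replicates: int = 3
    noise_sd: float = 0.5
    # entries: (gene_index, per-step effect in log2 units, consistent flag)
    planted_promoted: tuple[tuple[int, float, bool], ...] = ()
    planted_inhibited: tuple[tuple[int, float, bool], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be a positive integer")
        if len(self.contexts) != 2 or len(set(self.contexts)) != 2:
            raise ConfigError("contexts must be an ordered pair of distinct labels")
        if len(self.treatments) != 3 or len(set(self.treatments)) != 3:
            raise ConfigError("treatments must be an ordered triple of distinct labels")
        if self.replicates < 3:
            raise ConfigError("replicates must be >= 3")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be positive")
        prom = {g for g, _, _ in self.planted_promoted}
        inh = {g for g, _, _ in self.planted_inhibited}
        if prom & inh:
            raise ConfigError("planted_promoted and planted_inhibited must be disjoint")
        for g, eff, _ in self.planted_promoted + self.planted_inhibited:
            if not 0 <= g < self.n_genes:
                raise ConfigError(f"planted gene_id {g} outside [0, n_genes)")
            if not eff > 0:
                raise ConfigError(f"planted effect for gene_id {g} must be positive")


def simulate_expression(config: TrendSimConfig):
    """Simulate an expression study; returns (ExpressionStudy, truth frame).

    Truth is a DataFrame indexed by gene id with columns ``label`` (promoted /
    inhibited / null), ``effect`` and ``consistent``.
    """
    from .screen import ExpressionStudy  # local import: screen depends on jt only

    config.validate()
    rng = _child_rng(config.seed, "expression")
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    baseline = rng.uniform(6.0, 12.0, size=config.n_genes)

    # signed per-step slope per (gene, context); 0 for null genes
    slopes = np.zeros((config.n_genes, 2))
    labels = np.array(["null"] * config.n_genes, dtype=object)
    effect_col = np.zeros(config.n_genes)
    consistent_col = np.zeros(config.n_genes, dtype=bool)
    for sign, planted, label in (
        (1.0, config.planted_promoted, "promoted"),
        (-1.0, config.planted_inhibited, "inhibited"),
    ):
        for g, eff, consistent in planted:
            slopes[g, 0] = sign * eff
            slopes[g, 1] = sign * eff if consistent else -sign * eff
            labels[g] = label
            effect_col[g] = eff
            consistent_col[g] = consistent

    rows = []
    sample_ids = []
    design_rows = []
    cols = []
    for ci, ctx in enumerate(config.contexts):
        for ti, trt in enumerate(config.treatments):
            for r in range(1, config.replicates + 1):
                sid = f"{ctx}_{trt}_r{r}"
                sample_ids.append(sid)
                design_rows.append({"sample_id": sid, "context": ctx, "treatment": trt, "replicate": r})
                mean = baseline + slopes[:, ci] * ti
                cols.append(mean + rng.normal(0.0, config.noise_sd, size=config.n_genes))
    expr = pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=sample_ids)
    design = pd.DataFrame(design_rows).set_index("sample_id")
    study = ExpressionStudy(
        expression=expr,
        design=design,
        context_order=config.contexts,
        treatment_order=config.treatments,
    )
    truth = pd.DataFrame(
        {"label": labels, "effect": effect_col, "consistent": consistent_col},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return study, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(
    n_samples: int,
    target_shift: float,
    seed: int = 0,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    reference_ct: float = 20.0,
    target_ct: float = 25.0,
) -> tuple[CtTable, dict]:
    """Two-condition Ct table with a known planted fold change.

    The reference assay's Ct is constant in expectation across conditions;
    the target assay's Ct is shifted by ``target_shift`` cycles in the
    ``treated`` condition, so the true fold change of treated versus the
    ``control`` calibrator is ``2 ** -target_shift``.
    """
    if n_samples < 1:
        raise ConfigError("n_samples must be >= 1")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    rng = _child_rng(seed, "ct")
    rows = []
    for cond, shift in (("control", 0.0), ("treated", target_shift)):
        for s in range(1, n_samples + 1):
            sid = f"{cond}_{s}"
            for assay, base in (("target", target_ct + shift), ("reference", reference_ct)):
                for rep in range(1, n_replicates + 1):
                    ct = base + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append((sid, cond, assay, rep, ct))
    table = CtTable(pd.DataFrame(rows, columns=["sample_id", "condition", "assay", "replicate", "ct"]))
    truth = {"true_fc": 2.0 ** (-target_shift), "target_shift": target_shift}
    return table, truth


# ---------------------------------------------------------------------------
# meta-analysis study summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaSimConfig:
    """Case-control study summaries around a known standardized difference.

    Per-study true effects are drawn as ``true_smd + Normal(0, tau2)``
    (``tau2`` is a variance); each arm is then sampled as unit-variance
    normal data of the drawn size and summarised, so the study summaries
    carry realistic within-study sampling noise.
    """

    n_studies: int = 5
    true_smd: float = 1.01
    tau2: float = 0.05
    n_range: tuple[int, int] = (80, 120)
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ConfigError("n_studies must be >= 1")
        if self.tau2 < 0:
            raise ConfigError("tau2 must be non-negative")
        lo, hi = self.n_range
        if lo < 2 or hi < lo:
            raise ConfigError("n_range lower bound must be >= 2 and <= upper bound")


def simulate_meta_studies(config: MetaSimConfig) -> tuple[list[StudySummary], dict]:
    """Simulate study summaries; returns (studies, truth with per-study effects)."""
    config.validate()
    rng = _child_rng(config.seed, "meta")
    lo, hi = config.n_range
    studies, thetas = [], []
    for i in range(config.n_studies):
        theta = config.true_smd + np.sqrt(config.tau2) * rng.standard_normal()
        thetas.append(theta)
        n_case = int(rng.integers(lo, hi + 1))
        n_control = int(rng.integers(lo, hi + 1))
        case = rng.normal(theta, 1.0, n_case)
        control = rng.normal(0.0, 1.0, n_control)
        studies.append(
            StudySummary(
                study_id=f"study{i + 1}",
                n_case=n_case,
                mean_case=float(case.mean()),
                sd_case=float(case.std(ddof=1)),
                n_control=n_control,
                mean_control=float(control.mean()),
                sd_control=float(control.std(ddof=1)),
            )
        )
    truth = {"true_smd": config.true_smd, "tau2": config.tau2, "study_effects": thetas}
    return studies, truth
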