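"""Genome-wide trend screen for miRNA-regulated genes.

The screen classifies each gene as *promoted* or *inhibited* by the miRNA
from the sign of the rank correlation between expression and the ordered
treatment factor (inhibitor < control < mimic, i.e. increasing miRNA
activity), then tests the monotone trend one-sided in the fitted direction
with the Jonckheere-Terpstra statistic and permutation empirical p-values:
per context (monolayer, cancer-stem-cell culture), and combined across the
monolayer-to-CSC transition over six ordered groups (the combined null
permutes labels across contexts, so the transition itself is under test; a
context-blocked variant is available).  A gene is *consistent with the working
hypothesis* when its fitted direction is identical in both contexts and both
per-context trends are significant at the chosen level.

Multiple-testing options: plain per-gene empirical p-values (``none``),
Benjamini-Hochberg over genes (``bh``, default reporting mode), or
Westfall-Young max-T family-wise correction sharing one permutation stream
across genes (``maxt``).
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .jt import (
    _comparison_matrix,
    _ordered_pair_indices,
    _perm_jt,
    jt_permutation_p,
    jt_statistic,
    permuted_indices,
)
from .pool import bh_adjust

__all__ = [
    "ExpressionStudy",
    "DegenerateGene",
    "classify_direction",
    "combined_transition_trend",
    "TrendScreen",
    "TrendScreenResults",
    "screen",
]

THREE_ARM = ("inhibitor", "control", "mimic")
FOUR_ARM = ("inhibitor", "inhibitor_control", "mimic_control", "mimic")
# ordinal code of each treatment on the miRNA-activity axis; the two control
# arms of a four-arm design are tied at the middle level
_FOUR_ARM_CODES = {"inhibitor": 0, "inhibitor_control": 1, "mimic_control": 1, "mimic": 2}


class DegenerateGene(ValueError):
    """Gene with no expression variation; no direction can be fitted."""


@dataclass
class ExpressionStudy:
    """Gene x sample log2 expression matrix with a context x treatment design.

    ``design`` is indexed by sample id with columns ``context``, ``treatment``
    and ``replicate``; every (context, treatment) cell needs >= 2 replicates.
    """

    expression: pd.DataFrame
    design: pd.DataFrame
    context_order: tuple[str, str] = ("monolayer", "csc")
    treatment_order: tuple[str, ...] = THREE_ARM

    def __post_init__(self):
        if self.expression.index.duplicated().any():
            dup = self.expression.index[self.expression.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        missing = [s for s in self.expression.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from the design: {missing}")
        self.design = self.design.loc[self.expression.columns]
        self.design.index.name = "sample_id"
        bad_ctx = set(self.design["context"]) - set(self.context_order)
        if bad_ctx:
            raise ValueError(f"contexts outside the declared order: {sorted(bad_ctx)}")
        bad_trt = set(self.design["treatment"]) - set(self.treatment_order)
        if bad_trt:
            raise ValueError(f"treatments outside the declared order: {sorted(bad_trt)}")
        cell_sizes = self.design.groupby(["context", "treatment"]).size()
        if (cell_sizes < 2).any():
            bad = cell_sizes.index[cell_sizes < 2][0]
            raise ValueError(f"design cell {bad} has fewer than 2 replicates")

    @property
    def gene_ids(self) -> list:
        return list(self.expression.index)

    @property
    def contexts(self) -> tuple[str, str]:
        return self.context_order

    def treatment_codes(self) -> np.ndarray:
        """Ordinal miRNA-activity code per sample (0 = inhibitor end)."""
        if set(self.treatment_order) == set(FOUR_ARM):
            mapping = _FOUR_ARM_CODES
        else:
            mapping = {t: i for i, t in enumerate(self.treatment_order)}
        return self.design["treatment"].map(mapping).to_numpy()

    def context_codes(self) -> np.ndarray:
        mapping = {c: i for i, c in enumerate(self.context_order)}
        return self.design["context"].map(mapping).to_numpy()

    def combined_codes(self) -> np.ndarray:
        """Six-group ordering along the monolayer-to-CSC transition."""
        return self.context_codes() * 3 + self.treatment_codes()

    def values(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.expression.index:
            raise KeyError(f"unknown gene {gene_id!r}")
        return self.expression.loc[gene_id].to_numpy(dtype=float)


def _direction_from_tau(codes: np.ndarray, values: np.ndarray) -> str:
    """Sign of the rank correlation; ties break toward 'promoted'."""
    if np.ptp(values) == 0:
        raise DegenerateGene("all expression values are equal")
    tau = stats.kendalltau(codes, values).statistic
    if np.isnan(tau) or tau >= 0:
        return "promoted"
    return "inhibited"


def classify_direction(study: ExpressionStudy, gene_id: str) -> str:
    """'promoted' (expression rises with miRNA activity) or 'inhibited'.

    Uses the rank correlation between the ordered treatment factor and
    expression pooled across contexts; a flat gene raises ``DegenerateGene``.
    """
    return _direction_from_tau(study.treatment_codes(), study.values(gene_id))


def _gene_rng(run_seed, gene_id: str) -> np.random.Generator:
    """Deterministic per-gene stream, independent of gene order."""
    digest = hashlib.sha256(f"{run_seed}:{gene_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def combined_transition_trend(
    study: ExpressionStudy,
    gene_id: str,
    direction: str | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    exact: bool = False,
    stratify_contexts: bool = False,
) -> float:
    """Empirical p for a monotone trend across all six (context, treatment)
    groups ordered along the monolayer-to-CSC transition.

    Promoted genes are tested against the increasing alternative, inhibited
    genes against the decreasing alternative on the same six-group layout.
    Labels are permuted across contexts by default: the cross-context pair
    count of the JT statistic is invariant under within-context shuffles, so
    only the unstratified null makes the transition component testable.
    ``stratify_contexts=True`` restores the context-blocked null, which
    reduces the test to the pooled within-context trend.
    """
    if set(study.design["context"]) != set(study.context_order):
        missing = set(study.context_order) - set(study.design["context"])
        raise ValueError(f"combined trend needs both contexts; missing {sorted(missing)}")
    v = study.values(gene_id)
    if direction is None:
        direction = classify_direction(study, gene_id)
    jt_dir = "increasing" if direction == "promoted" else "decreasing"
    codes = study.combined_codes()
    if exact:
        return jt_permutation_p(v, codes, jt_dir, exact=True)
    return jt_permutation_p(
        v,
        codes,
        jt_dir,
        n_perm=n_perm,
        seed=_gene_rng(seed, gene_id),
        strata=study.context_codes() if stratify_contexts else None,
    )


class TrendScreen:
    """Model object for the genome-wide trend screen.

    Parameters
    ----------
    study
        The expression study (both contexts measured).
    alpha
        Per-context significance level for the consistency call.
    n_perm
        Permutations per empirical p-value.
    correction
        ``"none"``, ``"bh"`` (Benjamini-Hochberg over genes, default) or
        ``"maxt"`` (Westfall-Young family-wise, shared permutation stream).
    gene_list
        Optional curated gene ids to intersect the hits with.
    """

    def __init__(
        self,
        study: ExpressionStudy,
        alpha: float = 0.05,
        n_perm: int = 10_000,
        correction: str = "bh",
        gene_list: Sequence[str] | None = None,
        stratify_contexts: bool = False,
    ):
        if correction not in ("none", "bh", "maxt"):
            raise ValueError(f"unknown correction {correction!r}")
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if set(study.design["context"]) != set(study.context_order):
            missing = set(study.context_order) - set(study.design["context"])
            raise ValueError(f"the screen needs both contexts; missing {sorted(missing)}")
        self.study = study
        self.alpha = alpha
        self.n_perm = n_perm
        self.correction = correction
        self.gene_list = list(gene_list) if gene_list is not None else None
        self.stratify_contexts = stratify_contexts

    # ------------------------------------------------------------------
    def fit(self, seed: int | None = 0) -> "TrendScreenResults":
        study = self.study
        trt = study.treatment_codes()
        ctx = study.context_codes()
        comb = study.combined_codes()
        ctx_masks = [ctx == i for i in range(2)]

        rows = []
        for gid in study.gene_ids:
            v = study.values(gid)
            try:
                direction = _direction_from_tau(trt, v)
            except DegenerateGene:
                rows.append(
                    dict(
                        gene_id=gid,
                        direction=None,
                        dir_mono=None,
                        dir_csc=None,
                        jt_mono=np.nan,
                        jt_csc=np.nan,
                        jt_combined=np.nan,
                        p_trend_mono=np.nan,
                        p_trend_csc=np.nan,
                        p_trend=np.nan,
                        degenerate=True,
                    )
                )
                continue
            jt_dir = "increasing" if direction == "promoted" else "decreasing"
            rng = _gene_rng(seed, gid)
            per_ctx = {}
            for ci, mask in enumerate(ctx_masks):
                vv, gg = v[mask], trt[mask]
                try:
                    per_ctx[ci] = {
                        "dir": _direction_from_tau(gg, vv),
                        "jt": jt_statistic(vv, gg),
                        "p": jt_permutation_p(vv, gg, jt_dir, n_perm=self.n_perm, seed=rng),
                    }
                except DegenerateGene:
                    per_ctx[ci] = {"dir": None, "jt": jt_statistic(vv, gg), "p": np.nan}
            p_comb = jt_permutation_p(
                v,
                comb,
                jt_dir,
                n_perm=self.n_perm,
                seed=rng,
                strata=ctx if self.stratify_contexts else None,
            )
            rows.append(
                dict(
                    gene_id=gid,
                    direction=direction,
                    dir_mono=per_ctx[0]["dir"],
                    dir_csc=per_ctx[1]["dir"],
                    jt_mono=per_ctx[0]["jt"],
                    jt_csc=per_ctx[1]["jt"],
                    jt_combined=jt_statistic(v, comb),
                    p_trend_mono=per_ctx[0]["p"],
                    p_trend_csc=per_ctx[1]["p"],
                    p_trend=p_comb,
                    degenerate=False,
                )
            )
        table = pd.DataFrame(rows).set_index("gene_id")

        tested = ~table["degenerate"]
        if self.correction == "bh":
            for col in ("p_trend_mono", "p_trend_csc", "p_trend"):
                adj = np.full(len(table), np.nan)
                ok = tested & table[col].notna()
                adj[ok.to_numpy()] = bh_adjust(table.loc[ok, col].to_numpy())
                table[col.replace("p_trend", "q_trend")] = adj
            use_mono, use_csc = table["q_trend_mono"], table["q_trend_csc"]
        elif self.correction == "maxt":
            self._maxt(table, seed)
            use_mono, use_csc = table["fwe_p_mono"], table["fwe_p_csc"]
        else:
            use_mono, use_csc = table["p_trend_mono"], table["p_trend_csc"]

        same_dir = (
            table["dir_mono"].notna()
            & (table["dir_mono"] == table["dir_csc"])
        )
        table["consistent_with_hypothesis"] = (
            tested & same_dir & (use_mono <= self.alpha) & (use_csc <= self.alpha)
        )

        curated = None
        if self.gene_list is not None:
            curated = [g for g in self.gene_list if g in table.index]
            table["in_curated_list"] = table.index.isin(curated)

        counts = {
            "n_genes": int(len(table)),
            "n_degenerate": int(table["degenerate"].sum()),
            "n_tested": int(tested.sum()),
            "n_consistent": int(table["consistent_with_hypothesis"].sum()),
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "correction": self.correction,
            "seed": seed,
        }
        if curated is not None:
            counts["n_curated_measured"] = len(curated)
            counts["n_consistent_in_curated"] = int(
                table.loc[curated, "consistent_with_hypothesis"].sum()
            )
        return TrendScreenResults(model=self, table=table, counts=counts, seed=seed)

    # ------------------------------------------------------------------
    def _maxt(self, table: pd.DataFrame, seed) -> None:
        """Westfall-Young single-step max-T adjusted p-values, one shared
        permutation stream per test family (monolayer, CSC, combined)."""
        study = self.study
        trt = study.treatment_codes()
        ctx = study.context_codes()
        comb = study.combined_codes()
        families = {
            "fwe_p_mono": (ctx == 0, trt, None),
            "fwe_p_csc": (ctx == 1, trt, None),
            "fwe_p": (
                np.ones_like(ctx, dtype=bool),
                comb,
                ctx if self.stratify_contexts else None,
            ),
        }
        genes = [g for g in table.index if not table.loc[g, "degenerate"]]
        signs = {
            g: 1.0 if table.loc[g, "direction"] == "promoted" else -1.0 for g in genes
        }
        for col, (mask, codes_all, strata_all) in families.items():
            codes = codes_all[mask]
            strata = strata_all[mask] if strata_all is not None else None
            rng = _gene_rng(seed, f"__maxt__{col}")
            idx = permuted_indices(int(mask.sum()), self.n_perm, rng, strata=strata)
            a_idx, b_idx = _ordered_pair_indices(codes)
            max_z = np.full(self.n_perm, -np.inf)
            z_obs = {}
            for g in genes:
                v = study.values(g)[mask]
                C = _comparison_matrix(v)
                obs = float(C[a_idx, b_idx].sum())
                perm = _perm_jt(C, idx, a_idx, b_idx)
                m, s = perm.mean(), perm.std()
                if s == 0:
                    z_obs[g] = 0.0
                    continue
                z_obs[g] = signs[g] * (obs - m) / s
                np.maximum(max_z, signs[g] * (perm - m) / s, out=max_z)
            adj = np.full(len(table), np.nan)
            for i, g in enumerate(table.index):
                if g in z_obs:
                    adj[i] = (1 + int((max_z >= z_obs[g] - 1e-12).sum())) / (self.n_perm + 1)
            table[col] = adj


@dataclass
class TrendScreenResults:
    """Per-gene trend results with stage counts and ranking helpers."""

    model: TrendScreen
    table: pd.DataFrame
    counts: dict
    seed: int | None

    @property
    def consistent_genes(self) -> list:
        return list(self.table.index[self.table["consistent_with_hypothesis"]])

    def rank_scores(self, on: str = "p_trend") -> pd.Series:
        """Signed -log10 empirical p (promoted positive) for enrichment."""
        p = self.table[on]
        sign = self.table["direction"].map({"promoted": 1.0, "inhibited": -1.0})
        scores = -np.log10(p) * sign
        return scores.dropna()

    def ranking(self, on: str = "p_trend") -> tuple[list, np.ndarray]:
        """Gene ids and scores sorted by decreasing score."""
        s = self.rank_scores(on=on).sort_values(ascending=False)
        return list(s.index), s.to_numpy()

    def sample_permutation_scores(
        self, n_perm: int, seed: int | None = 0, stratify_contexts: bool = False
    ) -> tuple[list, np.ndarray]:
        """Design-permuted ranking scores for sample-mode enrichment.

        For each stratified permutation of the treatment labels, every
        gene's combined-trend JT statistic is standardised by its exact
        permutation-null moments and signed so promoted trends are positive;
        the observed ranking uses the same score, so permuted and observed
        rankings are directly comparable.  Returns (gene_ids, matrix of
        shape (n_perm, n_genes)).
        """
        from .jt import jt_null_moments

        study = self.model.study
        comb = study.combined_codes()
        ctx = study.context_codes()
        genes = [g for g in self.table.index if not self.table.loc[g, "degenerate"]]
        m, var = jt_null_moments(comb)
        s = np.sqrt(var)
        rng = _gene_rng(seed, "__sample_scores__")
        idx = permuted_indices(
            len(comb), n_perm, rng, strata=ctx if stratify_contexts else None
        )
        a_idx, b_idx = _ordered_pair_indices(comb)
        out = np.empty((n_perm, len(genes)))
        for j, g in enumerate(genes):
            C = _comparison_matrix(study.values(g))
            out[:, j] = (_perm_jt(C, idx, a_idx, b_idx) - m) / s
        return genes, out

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Trend screen (Jonckheere-Terpstra, permutation p-values)",
            f"  genes: {c['n_genes']}  tested: {c['n_tested']}  degenerate: {c['n_degenerate']}",
            f"  alpha: {c['alpha']}  n_perm: {c['n_perm']}  correction: {c['correction']}  seed: {c['seed']}",
            f"  consistent with the working hypothesis: {c['n_consistent']}",
        ]
        if "n_curated_measured" in c:
            lines.append(
                f"  curated list: {c['n_curated_measured']} measured, "
                f"{c['n_consistent_in_curated']} consistent"
            )
        return "\n".join(lines)


def screen(
    study: ExpressionStudy,
    gene_list: Sequence[str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = 0,
    correction: str = "bh",
) -> TrendScreenResults:
    """Run the full per-gene trend screen (functional front end)."""
    return TrendScreen(
        study, alpha=alpha, n_perm=n_perm, correction=correction, gene_list=gene_list
    ).fit(seed=seed)
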