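"""Supervised ancestry-proportion estimation and panel evaluation.

Model
-----
Each individual carries 2M allele copies over M markers.  Conditional on the
individual's ancestry proportions q (a point on the K-simplex), every copy
independently originates from population k with probability q_k and is
allele 1 with that population's reference frequency f_mk.  The genotype
likelihood is a product of binomials with per-marker success probability
p_m = sum_k q_k f_mk:

    L(q) = prod_m C(2, g_m) p_m^{g_m} (1 - p_m)^{2 - g_m}

Reference frequencies F are held fixed (supervised estimation), so
individuals are independent and q is estimated per individual by EM from a
uniform start.  The E-step attributes each observed allele copy to source
populations in proportion to q_k f_mk (or q_k (1 - f_mk) for the other
allele); the M-step renormalizes the attributed copy counts.  The
log-likelihood is non-decreasing across iterations, a property the test
suite asserts on every fitted input.

Use :class:`SupervisedAdmixture` / :class:`SupervisedAdmixtureResults` for
the model-object interface, or :func:`estimate_proportions` for the
functional one.  Evaluation helpers compare ancestry estimated from a small
marker panel against genome-wide estimates per ancestry (Pearson correlation
and RMSE), including the permutation protocol over random sub-cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .datamodel import AncestryMatrix, DataError, GenotypeMatrix, SourceFreqs

__all__ = [
    "SupervisedAdmixture",
    "SupervisedAdmixtureResults",
    "estimate_proportions",
    "label_clusters",
    "evaluate_panel",
    "permutation_evaluate",
    "PermutationResult",
]


class SupervisedAdmixture:
    """Supervised admixture model for a genotyped cohort.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Allele-1 dosages; missing genotypes are skipped in the likelihood.
    source_freqs : SourceFreqs
        Fixed reference allele-1 frequencies per source population, clamped
        away from 0/1.  Only SNPs present in both inputs are used.
    """

    def __init__(self, genotypes: GenotypeMatrix, source_freqs: SourceFreqs):
        shared = [s for s in genotypes.snp_ids if s in set(source_freqs.snp_ids)]
        if not shared:
            raise DataError("genotypes and source frequencies share no SNPs")
        self.genotypes = genotypes.restrict(shared)
        self.F = source_freqs.freq.loc[shared].to_numpy(dtype=float)
        self.populations = source_freqs.populations
        self.snp_ids = shared

    @classmethod
    def from_dataframe(
        cls, dosages: pd.DataFrame, source_freqs: pd.DataFrame
    ) -> "SupervisedAdmixture":
        """Build from raw frames: dosages individuals x SNPs, frequencies
        SNPs x populations."""
        g = GenotypeMatrix(
            dosages.to_numpy(dtype=float),
            list(dosages.index),
            list(dosages.columns),
        )
        return cls(g, SourceFreqs(source_freqs.copy()))

    def loglike(self, q: np.ndarray) -> np.ndarray:
        """Per-individual log-likelihood (binomial constant omitted) at Q."""
        G = self.genotypes.dosage
        mask = ~np.isnan(G)
        G0 = np.nan_to_num(G)
        P = np.asarray(q) @ self.F.T
        ll = np.where(mask, G0 * np.log(P) + (2.0 - G0) * np.log1p(-P), 0.0)
        return ll.sum(axis=1)

    def fit(self, tol: float = 1e-7, max_iter: int = 1000) -> "SupervisedAdmixtureResults":
        """EM from uniform initialization until the relative log-likelihood
        change drops below ``tol`` (default 1e-7) or ``max_iter`` iterations."""
        G = self.genotypes.dosage
        n, m = G.shape
        k = len(self.populations)
        mask = ~np.isnan(G)
        n_obs = mask.sum(axis=1)
        empty = n_obs == 0
        if empty.any():
            bad = [self.genotypes.individual_ids[i] for i in np.where(empty)[0]]
            warnings.warn(
                f"{len(bad)} individual(s) with no observed genotypes: {bad[:5]}",
                stacklevel=2,
            )

        if k == 1:
            q = np.ones((n, 1))
            ll = self.loglike(q)
            q[empty] = np.nan
            ll = np.where(empty, np.nan, ll)
            return self._results(q, ll, np.array([np.nansum(ll)]), 0, True)

        G0 = np.nan_to_num(G)
        W1 = np.where(mask, G0, 0.0)          # observed allele-1 copies
        W0 = np.where(mask, 2.0 - G0, 0.0)    # observed allele-2 copies
        F = self.F
        Q = np.full((n, k), 1.0 / k)
        ll = self._ll(Q, W1, W0, F)
        history = [float(np.nansum(np.where(empty, 0.0, ll)))]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            P = Q @ F.T
            E1 = W1 / P
            E0 = W0 / (1.0 - P)
            Q_new = Q * (E1 @ F + E0 @ (1.0 - F))
            denom = Q_new.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore"):
                Q_new = np.where(denom > 0, Q_new / np.where(denom == 0, 1.0, denom), Q)
            ll_new = self._ll(Q_new, W1, W0, F)
            active = ~empty
            rel = np.abs(ll_new[active] - ll[active]) / (np.abs(ll[active]) + 1e-300)
            Q, ll = Q_new, ll_new
            history.append(float(np.nansum(np.where(empty, 0.0, ll))))
            if rel.size == 0 or rel.max() < tol:
                converged = True
                break
        Q = Q.copy()
        Q[empty] = np.nan
        ll = np.where(empty, np.nan, ll)
        return self._results(Q, ll, np.asarray(history), it, converged)

    @staticmethod
    def _ll(Q: np.ndarray, W1: np.ndarray, W0: np.ndarray, F: np.ndarray) -> np.ndarray:
        P = Q @ F.T
        return (W1 * np.log(P) + W0 * np.log1p(-P)).sum(axis=1)

    def _results(
        self, q: np.ndarray, ll: np.ndarray, history: np.ndarray, n_iter: int, converged: bool
    ) -> "SupervisedAdmixtureResults":
        qdf = pd.DataFrame(
            q, index=pd.Index(self.genotypes.individual_ids, name="individual_id"),
            columns=self.populations,
        )
        return SupervisedAdmixtureResults(
            model=self,
            ancestry=AncestryMatrix(qdf),
            loglik=pd.Series(ll, index=qdf.index, name="loglik"),
            loglik_path=history,
            n_iter=n_iter,
            converged=converged,
        )


@dataclass
class SupervisedAdmixtureResults:
    """Fitted ancestry proportions with their likelihood diagnostics."""

    model: SupervisedAdmixture
    ancestry: AncestryMatrix
    loglik: pd.Series
    loglik_path: np.ndarray
    n_iter: int
    converged: bool

    @property
    def total_loglik(self) -> float:
        return float(np.nansum(self.loglik.to_numpy()))

    def summary(self) -> str:
        q = self.ancestry.q
        lines = [
            "Supervised admixture estimation",
            "=" * 47,
            f"Individuals: {len(q)}    Markers: {len(self.model.snp_ids)}"
            f"    Populations: {len(self.model.populations)}",
            f"EM iterations: {self.n_iter}    converged: {self.converged}",
            f"Total log-likelihood: {self.total_loglik:.4f}",
            "",
            f"{'ancestry':<16}{'mean':>8}{'median':>9}{'IQR':>16}",
            "-" * 49,
        ]
        for pop in q.columns:
            col = q[pop].dropna()
            q1, q3 = (col.quantile(0.25), col.quantile(0.75)) if len(col) else (np.nan, np.nan)
            lines.append(
                f"{pop:<16}{col.mean():>8.4f}{col.median():>9.4f}"
                f"{'':>4}{q1:.3f}-{q3:.3f}"
            )
        return "\n".join(lines)


def estimate_proportions(
    genotypes: GenotypeMatrix,
    source_freqs: SourceFreqs,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> tuple[AncestryMatrix, float]:
    """Functional wrapper: fitted ancestry matrix and final total log-likelihood."""
    res = SupervisedAdmixture(genotypes, source_freqs).fit(tol=tol, max_iter=max_iter)
    return res.ancestry, res.total_loglik


def label_clusters(
    q_sources: AncestryMatrix, source_labels: Sequence[str]
) -> dict[str, str]:
    """Identify which ancestry cluster corresponds to which source population.

    ``q_sources`` holds estimated proportions for reference individuals of
    known origin (``source_labels``, one per row).  The mean proportion of
    each cluster is computed per source, and clusters are assigned one-to-one
    to sources so that the sum of assigned means is maximal (optimal linear
    assignment; coincides with per-source argmax whenever that is
    conflict-free).  Returns a cluster -> source map.
    """
    labels = np.asarray(source_labels, dtype=object)
    sources = list(dict.fromkeys(labels))
    clusters = q_sources.populations
    if len(clusters) < len(sources):
        raise DataError(
            f"{len(clusters)} clusters cannot label {len(sources)} sources"
        )
    means = np.zeros((len(sources), len(clusters)))
    qv = q_sources.q.to_numpy(dtype=float)
    for i, src in enumerate(sources):
        rows = labels == src
        if not rows.any():
            raise DataError(f"source {src!r} has no reference individuals")
        means[i] = np.nanmean(qv[rows], axis=0)
    row_ind, col_ind = linear_sum_assignment(-means)
    return {clusters[c]: sources[r] for r, c in zip(row_ind, col_ind)}


def evaluate_panel(
    q_aims: AncestryMatrix,
    q_genomewide: AncestryMatrix,
    mapping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-ancestry Pearson correlation and RMSE between two ancestry matrices.

    ``mapping`` optionally renames the AIM-estimate clusters to the
    genome-wide ancestry labels before comparison.  A zero-variance column
    (or fewer than two individuals) makes the correlation undefined — it is
    reported as NaN with ``correlation_defined`` False, never fabricated; the
    RMSE is computed regardless.
    """
    qa = q_aims.q.rename(columns=dict(mapping)) if mapping else q_aims.q
    qg = q_genomewide.q
    if list(qa.index) != list(qg.index):
        qa = qa.loc[qg.index]
    rows = []
    for anc in qg.columns:
        if anc not in qa.columns:
            raise DataError(f"ancestry {anc!r} missing from AIM estimates")
        x = qa[anc].to_numpy(dtype=float)
        y = qg[anc].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        n = int(ok.sum())
        rmse = float(np.sqrt(np.mean((x - y) ** 2))) if n else np.nan
        # a column is constant (correlation undefined) when all values are
        # equal; std() is unsuitable here since it picks up float noise
        varying = n >= 2 and np.ptp(x) > 0 and np.ptp(y) > 0
        if varying:
            corr = float(np.corrcoef(x, y)[0, 1])
            defined = True
        else:
            corr, defined = np.nan, False
        rows.append((anc, corr, defined, rmse, n))
    return pd.DataFrame(
        rows, columns=["ancestry", "correlation", "correlation_defined", "rmse", "n"]
    )


@dataclass
class PermutationResult:
    """Correlation/RMSE distribution over random sub-cohorts plus the
    full-cohort reference values."""

    draws: pd.DataFrame  # draw, ancestry, correlation, correlation_defined, rmse, n
    full: pd.DataFrame
    subset_size: int
    n_draws: int
    seed: int


def permutation_evaluate(
    genotypes: GenotypeMatrix,
    f_panel: SourceFreqs,
    f_genomewide: SourceFreqs,
    subset_size: int = 100,
    n_draws: int = 100,
    seed: int = 1,
) -> PermutationResult:
    """Evaluate panel accuracy on repeated random sub-cohorts.

    Draws ``n_draws`` uniform subsets of ``subset_size`` individuals without
    replacement (seeded) and computes per-ancestry correlation between
    panel-based and genome-wide ancestry estimates within each subset.
    Because the supervised model estimates each individual independently,
    proportions are fitted once on the full cohort and the per-draw metrics
    are computed on the corresponding rows.
    """
    n = genotypes.n_individuals
    if subset_size > n:
        raise DataError(f"subset_size {subset_size} exceeds cohort size {n}")
    q_panel, _ = estimate_proportions(genotypes, f_panel)
    q_gw, _ = estimate_proportions(genotypes, f_genomewide)
    full = evaluate_panel(q_panel, q_gw)
    rng = np.random.default_rng(seed)
    frames = []
    for d in range(n_draws):
        rows = rng.choice(n, size=subset_size, replace=False)
        sub_a = AncestryMatrix(q_panel.q.iloc[rows])
        sub_g = AncestryMatrix(q_gw.q.iloc[rows])
        rep = evaluate_panel(sub_a, sub_g)
        rep.insert(0, "draw", d)
        frames.append(rep)
    draws = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["draw", "ancestry", "correlation", "correlation_defined", "rmse", "n"]
        )
    )
    return PermutationResult(draws, full, subset_size, n_draws, seed)
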