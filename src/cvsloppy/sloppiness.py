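"""Fisher information, parameter influence and sloppiness classification.

The Fisher information matrix is built from the total-order sensitivity
matrix as F = S^T S, summarising how strongly the chosen measurement set
constrains the parameters.  Its eigen-decomposition yields (i) a
per-parameter influence score

    E_i = sum_j |mu_j Q_ij| / sum_j |mu_j|,

the eigenvalue-weighted aggregate of parameter i's loadings on the
principal components (0 <= E_i <= 1; larger means more identifiable), with
the sums running over the eigenvalues above the numerical-zero threshold,
and (ii) a sloppiness verdict: the system is sloppy when the retained
eigenvalues are spread over at least six orders of magnitude AND
approximately uniformly spaced on a log scale (largest adjacent log-gap at
most twice the mean gap; the factor is a convention, exposed in the
diagnostics so users can re-classify).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gsa import SensitivityMatrix

__all__ = [
    "FisherInformation",
    "EigenSpectrum",
    "InfluenceRanking",
    "SloppinessVerdict",
    "fisher_information",
    "eigenspectrum",
    "influence_scores",
    "rank_influential",
    "spectrum_span",
    "classify_sloppiness",
]


@dataclass(frozen=True)
class FisherInformation:
    F: np.ndarray
    parameter_names: tuple[str, ...]
    provenance: str = ""
    dropped_outputs: tuple[int, ...] = ()

    @property
    def n(self) -> int:
        return self.F.shape[0]


@dataclass(frozen=True)
class EigenSpectrum:
    """Descending eigenvalues with matching eigenvector columns.

    ``zero_threshold`` = lambda_max * n * machine-epsilon separates genuine
    information directions from numerical noise.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    parameter_names: tuple[str, ...]
    zero_threshold: float

    @property
    def retained(self) -> np.ndarray:
        """Boolean mask of eigenvalues above the numerical-zero threshold."""
        return self.eigenvalues > self.zero_threshold

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass(frozen=True)
class InfluenceRanking:
    scores: np.ndarray                       # E_i per parameter, input order
    parameter_names: tuple[str, ...]
    set_id: str = ""
    threshold: float = 0.01

    @property
    def ordered(self) -> list[tuple[str, float]]:
        """(parameter, E) pairs with E > threshold, by descending E with a
        deterministic name tie-break."""
        pairs = [(n, float(e)) for n, e
                 in zip(self.parameter_names, self.scores)
                 if e > self.threshold]
        return sorted(pairs, key=lambda p: (-p[1], p[0]))

    @property
    def n_influential(self) -> int:
        return len(self.ordered)

    def score(self, name: str) -> float:
        return float(self.scores[self.parameter_names.index(name)])


@dataclass(frozen=True)
class SloppinessVerdict:
    sloppy: bool
    span_decades: float
    void_fraction: float          # largest adjacent log-gap / span
    log_gaps: np.ndarray
    n_retained: int
    note: str = ""

    @property
    def label(self) -> str:
        return "sloppy" if self.sloppy else "not_sloppy"


# ---------------------------------------------------------------------------

def fisher_information(S_total: SensitivityMatrix | np.ndarray,
                       parameter_names: tuple[str, ...] | None = None,
                       provenance: str = "") -> FisherInformation:
    """F = S^T S, symmetrised to kill round-off asymmetry.

    Undefined (NaN) sensitivity rows - outputs whose ensemble variance was
    zero - are dropped before the product and recorded.
    """
    if isinstance(S_total, SensitivityMatrix):
        if parameter_names is None:
            parameter_names = S_total.parameter_names
        S = S_total.values
    else:
        S = np.asarray(S_total, dtype=float)
        if parameter_names is None:
            parameter_names = tuple(f"p{i}" for i in range(S.shape[1]))
    bad = np.flatnonzero(~np.isfinite(S).all(axis=1))
    if bad.size:
        S = np.delete(S, bad, axis=0)
    if S.shape[0] == 0:
        raise ValueError("no finite sensitivity rows left")
    F = S.T @ S
    F = 0.5 * (F + F.T)
    return FisherInformation(F, tuple(parameter_names), provenance,
                             tuple(int(b) for b in bad))


def eigenspectrum(F: FisherInformation) -> EigenSpectrum:
    """Full symmetric eigen-decomposition, eigenvalues descending.

    Eigenvector signs are canonicalised (largest-magnitude component
    positive) for reproducible serialisation; the influence score uses
    absolute values and is unaffected.
    """
    if not np.all(np.isfinite(F.F)):
        raise ValueError("non-finite entries in the Fisher information")
    w, Q = np.linalg.eigh(F.F)
    order = np.argsort(w)[::-1]
    w = w[order]
    Q = Q[:, order]
    for j in range(Q.shape[1]):
        k = np.argmax(np.abs(Q[:, j]))
        if Q[k, j] < 0:
            Q[:, j] = -Q[:, j]
    lam_max = max(w[0], 0.0)
    thr = lam_max * F.n * np.finfo(float).eps
    return EigenSpectrum(w, Q, F.parameter_names, thr)


def influence_scores(spec: EigenSpectrum, set_id: str = "",
                     threshold: float = 0.01) -> InfluenceRanking:
    """E_i = sum_j |mu_j Q_ij| / sum_j |mu_j| over retained eigenvalues."""
    keep = spec.retained
    if not keep.any():
        raise ValueError("all-zero eigen-spectrum: influence undefined")
    mu = spec.eigenvalues[keep]
    Q = spec.eigenvectors[:, keep]
    E = (np.abs(Q) * np.abs(mu)[None, :]).sum(axis=1) / np.abs(mu).sum()
    return InfluenceRanking(E, spec.parameter_names, set_id, threshold)


def rank_influential(ranking: InfluenceRanking, threshold: float = 0.01):
    """Descending (rank, parameter, E) table of parameters with unrounded
    E above the threshold; a 2-decimal rendering column mirrors the
    reported tables."""
    import pandas as pd

    pairs = [(n, e) for n, e in zip(ranking.parameter_names, ranking.scores)
             if e > threshold]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return pd.DataFrame({
        "rank": np.arange(1, len(pairs) + 1),
        "parameter": [n for n, _ in pairs],
        "E": [e for _, e in pairs],
        "E_2dp": [f"{e:.2f}" for _, e in pairs],
    })


def spectrum_span(spec: EigenSpectrum) -> float:
    """log10(lambda_max / lambda_min) over all positive computed
    eigenvalues, numerical-noise eigenvalues included (this is the spread
    visible in a log-scale spectrum plot)."""
    pos = spec.eigenvalues[spec.eigenvalues > 0.0]
    if pos.size < 2:
        raise ValueError("need at least 2 positive eigenvalues")
    return float(np.log10(pos.max() / pos.min()))


def classify_sloppiness(spec: EigenSpectrum, span_min: float = 6.0,
                        max_void: float = 0.5) -> SloppinessVerdict:
    """Sloppy iff the retained eigenvalues spread approximately uniformly
    on a log scale over at least ``span_min`` decades.

    Uniformity is judged by the void fraction: the largest adjacent log10
    gap divided by the span.  A spectrum dominated by a single void -
    larger than ``max_void`` of the span, default one half - is a
    cliff-and-cluster pattern (a few stiff directions far above the rest),
    not the evenly filled ladder that defines sloppiness.  The guard is
    deliberately weak because individual gap sizes carry estimator noise;
    both knobs are conventions, reported in the diagnostics so users can
    re-classify.

    Fewer than 3 retained eigenvalues cannot exhibit a ladder and classify
    as not sloppy.
    """
    keep = spec.retained
    mu = spec.eigenvalues[keep]
    if mu.size < 3:
        return SloppinessVerdict(False, 0.0, np.nan, np.zeros(0),
                                 int(mu.size),
                                 "fewer than 3 retained eigenvalues")
    logs = np.log10(mu)                      # descending
    gaps = -np.diff(logs)
    span = float(logs[0] - logs[-1])
    if span == 0.0:
        return SloppinessVerdict(False, 0.0, 0.0, gaps, int(mu.size),
                                 "degenerate spectrum")
    void = float(gaps.max() / span)
    sloppy = span >= span_min and void <= max_void
    note = ""
    if span >= span_min and not sloppy:
        note = (f"span {span:.1f} decades but the largest log-gap covers "
                f"{void:.0%} of it: spacing not uniform")
    return SloppinessVerdict(bool(sloppy), span, void, gaps, int(mu.size),
                             note)
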