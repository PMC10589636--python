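"""Mutational-signature inference.

De novo extraction follows the iterated-NMF stability recipe: the catalog is
bootstrap-resampled per sample, factorized many times under the generalized
Kullback-Leibler objective with multiplicative updates, and the pooled
signature vectors are clustered by cosine distance; the consensus signature
of each cluster is its renormalized mean, and the factorization rank is
chosen by mean silhouette.  Supervised deconvolution of a catalog onto a
fixed signature set is non-negative least squares (the linear-combination
decomposition), optionally with per-signature relative-exposure cutoffs and
a cohort-level 5% absolute-exposure filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .catalogs import SCHEMES, MutationCatalog

log = logging.getLogger(__name__)


@dataclass
class SignatureMatrix:
    """Channels x K column-stochastic signature matrix."""

    scheme: str
    W: pd.DataFrame  # index: channel labels (canonical order), columns: names

    def __post_init__(self) -> None:
        channels = list(SCHEMES[self.scheme])
        if list(self.W.index) != channels:
            if set(self.W.index) != set(channels):
                raise ValueError(f"signature matrix channels do not match scheme {self.scheme}")
            self.W = self.W.reindex(channels)
        arr = self.W.to_numpy(dtype=float)
        if (arr < -1e-12).any():
            raise ValueError("signature matrix has negative entries")
        sums = arr.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"signature columns must sum to 1, got {sums}")

    @property
    def names(self) -> list[str]:
        return list(self.W.columns)

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def to_tsv(self, path) -> None:
        self.W.rename_axis("channel").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, scheme: str) -> "SignatureMatrix":
        return cls(scheme=scheme, W=pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class ExposureTable:
    """Samples x K absolute signature exposures (expected variant counts)."""

    absolute: pd.DataFrame
    provenance: str = "supervised"  # or "denovo"

    @property
    def relative(self) -> pd.DataFrame:
        totals = self.absolute.sum(axis=1)
        rel = self.absolute.div(totals.where(totals > 0, 1.0), axis=0)
        return rel

    def to_tsv(self, path) -> None:
        self.absolute.rename_axis("sample").to_csv(path, sep="\t")


@dataclass
class RankSelectionReport:
    per_k: pd.DataFrame  # index k; columns mean_silhouette, reconstruction_error, cophenetic
    chosen_k: int

    def to_tsv(self, path) -> None:
        self.per_k.rename_axis("k").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# KL-NMF with multiplicative updates
# ---------------------------------------------------------------------------

def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    eps = 1e-12
    mask = V > 0
    return float((V[mask] * np.log(V[mask] / (WH[mask] + eps))).sum()
                 - V.sum() + WH.sum())


def nmf_kl(V: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 400, tol: float = 1e-5,
           check_monotone: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Factorize V (channels x samples) ~ W @ H under generalized KL.

    Multiplicative updates from random non-negative initialization; the
    objective is checked for monotone decrease every 10 updates.
    Returns (W, H) with W column-normalized to sum 1.
    """
    eps = 1e-12
    m, n = V.shape
    scale = np.sqrt(V.mean() / k) + eps
    W = rng.random((m, k)) * scale + eps
    H = rng.random((k, n)) * scale + eps
    prev = _kl_divergence(V, W @ H)
    for it in range(max_iter):
        WH = W @ H + eps
        H *= W.T @ (V / WH) / (W.sum(axis=0)[:, None] + eps)
        WH = W @ H + eps
        W *= (V / WH) @ H.T / (H.sum(axis=1)[None, :] + eps)
        if (it + 1) % 10 == 0:
            obj = _kl_divergence(V, W @ H)
            if check_monotone and obj > prev + 1e-6 * (abs(prev) + 1.0):
                raise FloatingPointError(
                    f"KL objective increased at iteration {it + 1}: {prev} -> {obj}")
            if prev - obj < tol * (abs(prev) + 1.0):
                prev = obj
                break
            prev = obj
    col = W.sum(axis=0) + eps
    return W / col, H * col[:, None]


def _bootstrap_catalog(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-sample multinomial resampling with probabilities proportional to
    observed channel counts (standard signature-stability bootstrap)."""
    out = np.zeros_like(V, dtype=float)
    for j in range(V.shape[1]):
        total = V[:, j].sum()
        if total <= 0:
            continue
        p = V[:, j] / total
        out[:, j] = rng.multinomial(int(round(total)), p)
    return out


def extract_denovo(catalog: MutationCatalog, k_candidates,
                   n_iterations: int = 500, seed: int = 0,
                   bootstrap: bool = True,
                   ) -> tuple[dict[int, SignatureMatrix], RankSelectionReport, int]:
    """De novo signature extraction with silhouette-based rank selection.

    Returns ({k: consensus SignatureMatrix}, report, chosen k); chosen k
    maximizes mean silhouette (ties broken toward the smaller rank).
    """
    V = catalog.counts.to_numpy(dtype=float).T  # channels x samples
    if V.sum() <= 0:
        raise ValueError("catalog is all zeros; nothing to extract")
    if (V.sum(axis=0) > 0).sum() < 2:
        raise ValueError("need at least two samples with nonzero counts")
    channels = list(catalog.channel_labels)
    rng = np.random.default_rng(seed)
    results: dict[int, SignatureMatrix] = {}
    rows = []
    for k in sorted(k_candidates):
        vectors = []
        errors = []
        for _ in range(n_iterations):
            Vb = _bootstrap_catalog(V, rng) if bootstrap else V
            for _attempt in range(2):
                try:
                    W, H = nmf_kl(Vb, k, rng)
                    break
                except FloatingPointError:
                    log.warning("non-convergent NMF iteration retried (k=%d)", k)
            else:
                continue
            vectors.append(W.T)  # k rows of channel profiles
            errors.append(_kl_divergence(Vb, W @ H))
        X = np.vstack(vectors)  # (k * n_iterations) x channels
        # cosine clustering via k-means on L2-normalized vectors
        Xn = X / (np.linalg.norm(X, axis=1, keepdims=True) + 1e-12)
        km = KMeans(n_clusters=k, n_init=10,
                    random_state=int(rng.integers(2**31 - 1))).fit(Xn)
        labels = km.labels_
        if k >= 2 and len(set(labels)) >= 2:
            sil = float(silhouette_score(Xn, labels, metric="cosine"))
        else:
            sil = 1.0  # a single cluster of replicated rank-1 solutions
        # cophenetic correlation of the pooled signature vectors
        if len(X) > 2 and k >= 2:
            sub = Xn if len(Xn) <= 500 else Xn[rng.choice(len(Xn), 500, replace=False)]
            Z = linkage(sub, method="average", metric="cosine")
            coph = float(cophenet(Z, pdist(sub, metric="cosine"))[0])
        else:
            coph = float("nan")
        consensus = np.zeros((len(channels), k))
        for c in range(k):
            members = X[labels == c]
            mean = members.mean(axis=0) if len(members) else np.zeros(len(channels))
            consensus[:, c] = mean / (mean.sum() + 1e-12)
        # deterministic column order: by descending total catalog attribution
        order = np.argsort(-consensus.T @ V.sum(axis=1))
        consensus = consensus[:, order]
        names = [f"DN{k}.{i + 1}" for i in range(k)]
        results[k] = SignatureMatrix(
            scheme=catalog.scheme,
            W=pd.DataFrame(consensus, index=pd.Index(channels), columns=names))
        rows.append({"k": k, "mean_silhouette": sil,
                     "reconstruction_error": float(np.mean(errors)) if errors else float("nan"),
                     "cophenetic": coph})
    report = pd.DataFrame(rows).set_index("k")
    chosen = int(report["mean_silhouette"].idxmax())  # idxmax takes first (smallest k) on ties
    return results, RankSelectionReport(per_k=report, chosen_k=chosen), chosen


# ---------------------------------------------------------------------------
# matching and supervised fitting
# ---------------------------------------------------------------------------

def cosine_similarity(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def match_reference(denovo: SignatureMatrix, reference: SignatureMatrix,
                    threshold: float = 0.85) -> dict[str, tuple[str | None, float]]:
    """Greedy one-to-one assignment of de novo signatures to reference
    signatures in descending cosine similarity; pairs below ``threshold``
    are reported unmatched (novel) with their best similarity."""
    if list(denovo.W.index) != list(reference.W.index):
        raise ValueError("channel order mismatch between de novo and reference matrices")
    D = denovo.W.to_numpy(dtype=float)
    R = reference.W.to_numpy(dtype=float)
    sims = np.array([[cosine_similarity(D[:, i], R[:, j])
                      for j in range(R.shape[1])] for i in range(D.shape[1])])
    result: dict[str, tuple[str | None, float]] = {}
    pairs = sorted(((sims[i, j], i, j) for i in range(sims.shape[0])
                    for j in range(sims.shape[1])), reverse=True)
    used_d: set[int] = set()
    used_r: set[int] = set()
    for s, i, j in pairs:
        if i in used_d or j in used_r or s < threshold:
            continue
        result[denovo.names[i]] = (reference.names[j], float(s))
        used_d.add(i)
        used_r.add(j)
    for i in range(sims.shape[0]):
        if i not in used_d:
            best = int(np.argmax(sims[i]))
            result[denovo.names[i]] = (None, float(sims[i, best]))
    return result


def fit_exposures(catalog: MutationCatalog, signatures: SignatureMatrix,
                  per_signature_cutoffs=None) -> ExposureTable:
    """Per-sample NNLS deconvolution: min ||counts - W e||_2 s.t. e >= 0.

    With ``per_signature_cutoffs`` (relative-exposure floors, one per
    signature), signatures falling below their cutoff are zeroed and the
    remainder refit, iterated to a fixed point.
    """
    if catalog.scheme != signatures.scheme:
        raise ValueError("catalog and signature schemes differ")
    W = signatures.W.to_numpy(dtype=float)
    if np.any(W.sum(axis=0) <= 0):
        raise ValueError("signature matrix contains a zero column")
    cutoffs = np.zeros(W.shape[1]) if per_signature_cutoffs is None \
        else np.asarray(per_signature_cutoffs, dtype=float)
    rows = []
    for _, counts in catalog.counts.iterrows():
        v = counts.to_numpy(dtype=float)
        active = np.ones(W.shape[1], dtype=bool)
        e = np.zeros(W.shape[1])
        for _ in range(W.shape[1] + 1):
            e = np.zeros(W.shape[1])
            if active.any() and v.sum() > 0:
                sol, _res = nnls(W[:, active], v)
                e[active] = sol
            total = e.sum()
            rel = e / total if total > 0 else e
            drop = active & (rel < cutoffs) & (cutoffs > 0)
            if not drop.any():
                break
            active &= ~drop
        rows.append(e)
    abs_df = pd.DataFrame(rows, index=catalog.counts.index, columns=signatures.names)
    return ExposureTable(absolute=abs_df, provenance="supervised")


def filter_exposures_cohort(exposures: ExposureTable, catalog: MutationCatalog,
                            signatures: SignatureMatrix,
                            min_fraction: float = 0.05,
                            ) -> tuple[ExposureTable, list[str]]:
    """Drop signatures whose summed absolute exposure across the cohort is
    below ``min_fraction`` of the total cohort mutation count, then refit."""
    if list(exposures.absolute.index) != list(catalog.counts.index):
        raise ValueError("exposures and catalog cover different samples")
    total = float(catalog.counts.to_numpy().sum())
    sums = exposures.absolute.sum(axis=0)
    dropped = [name for name in exposures.absolute.columns
               if sums[name] < min_fraction * total]
    if not dropped:
        return exposures, []
    keep = [n for n in signatures.names if n not in dropped]
    if not keep:
        log.warning("cohort filter would drop every signature; keeping all")
        return exposures, []
    sub = SignatureMatrix(scheme=signatures.scheme, W=signatures.W[keep])
    return fit_exposures(catalog, sub), dropped
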