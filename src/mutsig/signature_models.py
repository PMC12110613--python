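"""Signature extraction, matching and exposure refitting.

De novo extraction factorizes a mutation catalog ``V`` (channels x samples)
into column-stochastic signature profiles ``W`` and non-negative exposures
``H`` by multiplicative-update NMF minimizing the generalized
Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ],

the Poisson-likelihood objective appropriate for count catalogs. Stability
over bootstrap-resampled catalogs (silhouette of cosine-clustered solutions)
drives rank selection. Cohort attribution against a reference signature set
(COSMIC-style TSV) uses per-sample non-negative least squares with pruning
of minor components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .catalog_io import MutationCatalog
from .channels import ChannelScheme, channel_labels

EPS = 1e-12


class DegenerateInputError(ValueError):
    """The catalog carries no counts to factorize."""


@dataclass
class SignatureSet:
    """Channels x signatures column-stochastic profile matrix."""

    channel_labels: list[str]
    signature_ids: list[str]
    profiles: np.ndarray
    provenance: str = "reference"  # {denovo, reference, decomposed}

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.channel_labels), len(self.signature_ids)):
            raise ValueError("profiles shape does not match labels/ids")
        if np.any(self.profiles < 0):
            raise ValueError("signature profiles must be non-negative")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("signature columns must sum to 1 (within 1e-8)")

    @property
    def n_signatures(self) -> int:
        return len(self.signature_ids)

    def scheme(self) -> ChannelScheme | None:
        for s in ChannelScheme:
            if tuple(self.channel_labels) == channel_labels(s):
                return s
        return None

    def column(self, signature_id: str) -> np.ndarray:
        return self.profiles[:, self.signature_ids.index(signature_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=self.channel_labels, columns=self.signature_ids)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "MutationType"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "reference") -> "SignatureSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        profiles = df.to_numpy(dtype=float)
        profiles = profiles / profiles.sum(axis=0, keepdims=True)
        return cls(list(df.index), list(df.columns), profiles, provenance)


@dataclass
class ExposureMatrix:
    """Samples x signatures attribution, absolute counts and per-sample shares."""

    sample_ids: list[str]
    signature_ids: list[str]
    absolute: np.ndarray
    relative: np.ndarray
    flagged_samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.absolute = np.asarray(self.absolute, dtype=float)
        self.relative = np.asarray(self.relative, dtype=float)
        shape = (len(self.sample_ids), len(self.signature_ids))
        if self.absolute.shape != shape or self.relative.shape != shape:
            raise ValueError("exposure matrices must be samples x signatures")
        rowsums = self.relative.sum(axis=1)
        if not np.all((np.abs(rowsums - 1) < 1e-8) | (rowsums < 1e-8)):
            raise ValueError("relative exposure rows must sum to 1 (or 0 for empty samples)")

    def abs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.absolute, index=self.sample_ids, columns=self.signature_ids)

    def rel_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.relative, index=self.sample_ids, columns=self.signature_ids)

    def to_tsv(self, path_absolute: str | Path, path_relative: str | Path) -> None:
        for df, p in ((self.abs_frame(), path_absolute), (self.rel_frame(), path_relative)):
            df.index.name = "sample_id"
            df.to_csv(p, sep="\t", float_format="%.10g")


@dataclass
class RankStats:
    rank: int
    silhouette: float
    reconstruction_error: float


@dataclass
class ExtractionReport:
    per_rank: dict[int, RankStats]
    selected_rank: int
    consensus: SignatureSet
    match_table: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# NMF core
# ---------------------------------------------------------------------------


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, EPS)
    mask = V > 0
    return float(np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum())


def nmf_factorize(
    catalog: MutationCatalog,
    rank: int,
    seed: int,
    tol: float = 1e-9,
    max_iter: int = 10_000,
    return_history: bool = False,
):
    """Multiplicative-update KL-NMF of a catalog.

    Returns ``(SignatureSet, ExposureMatrix, final_objective)``; with
    ``return_history=True`` a fourth element carries the per-iteration
    objective (non-increasing by construction of the updates).
    """
    V = catalog.counts.T.astype(float)  # channels x samples
    if V.sum() == 0:
        raise DegenerateInputError("all-zero catalog cannot be factorized")
    n_channels, n_samples = V.shape
    if not 1 <= rank <= min(n_samples, n_channels):
        raise ValueError(f"rank {rank} outside [1, {min(n_samples, n_channels)}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / rank)
    W = rng.uniform(0.5, 1.5, size=(n_channels, rank)) * scale
    H = rng.uniform(0.5, 1.5, size=(rank, n_samples)) * scale

    history = []
    prev = np.inf
    for _ in range(max_iter):
        WH = np.maximum(W @ H, EPS)
        H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], EPS)
        WH = np.maximum(W @ H, EPS)
        W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1)[None, :], EPS)
        obj = _kl_divergence(V, W @ H)
        history.append(obj)
        if prev - obj < tol * max(abs(prev), 1.0) and np.isfinite(prev):
            break
        prev = obj

    norms = np.maximum(W.sum(axis=0), EPS)
    W = W / norms
    H = H * norms[:, None]
    sig_ids = [f"denovo_{i + 1}" for i in range(rank)]
    signatures = SignatureSet(list(catalog.channel_labels), sig_ids, W, provenance="denovo")
    absolute = H.T
    rowsums = absolute.sum(axis=1, keepdims=True)
    relative = np.divide(absolute, rowsums, out=np.zeros_like(absolute), where=rowsums > 0)
    exposures = ExposureMatrix(list(catalog.sample_ids), sig_ids, absolute, relative)
    if return_history:
        return signatures, exposures, history[-1], history
    return signatures, exposures, history[-1]


def _bootstrap_catalog(catalog: MutationCatalog, rng: np.random.Generator) -> MutationCatalog:
    """Resample each sample's counts multinomially, preserving its burden."""
    counts = np.zeros_like(catalog.counts)
    for i, row in enumerate(catalog.counts):
        burden = row.sum()
        if burden > 0:
            counts[i] = rng.multinomial(burden, row / burden)
    return MutationCatalog(list(catalog.sample_ids), catalog.channel_scheme, counts)


def extract_denovo(
    catalog: MutationCatalog,
    rank_range: Sequence[int],
    n_restarts: int = 20,
    n_bootstraps: int = 30,
    seed: int = 0,
    reference: SignatureSet | None = None,
    min_cosine: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> ExtractionReport:
    """Bootstrap-stability de novo extraction with silhouette rank selection.

    For each candidate rank, the catalog is factorized across bootstrap
    resamples (the first "bootstrap" is the original catalog, so the
    degenerate single-bootstrap single-restart call reproduces a plain
    factorization) keeping the best of ``n_restarts`` per resample. Pooled
    solution signatures are partitioned into ``rank`` clusters by cosine
    distance; consensus profiles are the cluster medoids and stability is
    the minimum per-cluster mean silhouette (the weakest signature's
    reproducibility across bootstraps).
    """
    ranks = sorted(set(int(r) for r in rank_range))
    if not ranks:
        raise ValueError("rank_range is empty")
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    counter = 0

    def next_seed() -> int:
        nonlocal counter
        s = (seed + counter) % (2**31)
        counter += 1
        return s

    per_rank: dict[int, RankStats] = {}
    consensus_by_rank: dict[int, SignatureSet] = {}
    for rank in ranks:
        solutions = []
        errors = []
        for b in range(n_bootstraps):
            if b == 0:
                boot = catalog
            else:
                boot = _bootstrap_catalog(catalog, np.random.default_rng(next_seed()))
            best = None
            for _ in range(n_restarts):
                sigs, _, obj = nmf_factorize(boot, rank, next_seed(), tol=tol, max_iter=max_iter)
                if best is None or obj < best[1]:
                    best = (sigs, obj)
            solutions.append(best[0])
            errors.append(best[1] / max(boot.counts.sum(), 1))
        pooled = np.hstack([s.profiles for s in solutions])  # channels x (B*rank)
        X = (pooled / np.maximum(np.linalg.norm(pooled, axis=0), EPS)).T
        if rank == 1:
            labels = np.zeros(X.shape[0], dtype=int)
            sil = 1.0
        else:
            km = KMeans(n_clusters=rank, n_init=10, random_state=next_seed() % (2**31))
            labels = km.fit_predict(X)
            if len(set(labels)) < 2 or X.shape[0] <= rank:
                sil = 1.0 if X.shape[0] == rank else 0.0
            else:
                # stability = the weakest signature's mean silhouette: a rank
                # above the true one manifests as one irreproducible cluster,
                # which the pooled mean would mask
                per_point = silhouette_samples(X, labels, metric="cosine")
                sil = float(min(per_point[labels == c].mean() for c in set(labels)))
        medoids = []
        for c in range(rank):
            members = np.where(labels == c)[0]
            if members.size == 0:
                continue
            sub = X[members]
            d = 1 - sub @ sub.T  # cosine distances within cluster
            medoids.append(members[int(np.argmin(d.sum(axis=1)))])
        cols = pooled[:, sorted(medoids)]
        cols = cols / cols.sum(axis=0, keepdims=True)
        sig_ids = [f"denovo_{i + 1}" for i in range(cols.shape[1])]
        consensus_by_rank[rank] = SignatureSet(
            list(catalog.channel_labels), sig_ids, cols, provenance="denovo"
        )
        per_rank[rank] = RankStats(rank, sil, float(np.mean(errors)))

    selected = select_rank({r: s.silhouette for r, s in per_rank.items()})
    consensus = consensus_by_rank[selected]
    match = None
    if reference is not None:
        match = match_to_reference(consensus, reference, min_cosine=min_cosine)
    return ExtractionReport(per_rank, selected, consensus, match)


def select_rank(silhouettes: Mapping[int, float]) -> int:
    """Largest rank with mean silhouette >= 0.8; fallback: argmax (ties -> smaller)."""
    if not silhouettes:
        raise ValueError("no candidate ranks")
    qualifying = [r for r, s in silhouettes.items() if s >= 0.8]
    if qualifying:
        return max(qualifying)
    best = max(silhouettes.values())
    return min(r for r, s in silhouettes.items() if s == best)


# ---------------------------------------------------------------------------
# matching / refitting
# ---------------------------------------------------------------------------


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("profiles must share the channel ordering")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero profile")
    return float(np.dot(a, b) / (na * nb))


def match_to_reference(
    denovo: SignatureSet, reference: SignatureSet, min_cosine: float = 0.85
) -> pd.DataFrame:
    """Greedy one-to-one assignment of de novo to reference signatures.

    Pairs are taken in decreasing cosine order; de novo signatures whose
    best available match falls below ``min_cosine`` stay unmatched (flagged
    for decomposition).
    """
    if list(denovo.channel_labels) != list(reference.channel_labels):
        raise TypeError("channel schemes of the two signature sets differ")
    D, R = denovo.profiles, reference.profiles
    sim = (D / np.linalg.norm(D, axis=0)).T @ (R / np.linalg.norm(R, axis=0))
    pairs = sorted(
        ((sim[i, j], i, j) for i in range(sim.shape[0]) for j in range(sim.shape[1])),
        reverse=True,
    )
    used_d, used_r = set(), set()
    assignment: dict[int, tuple[int, float]] = {}
    for s, i, j in pairs:
        if i in used_d or j in used_r or s < min_cosine:
            continue
        assignment[i] = (j, s)
        used_d.add(i)
        used_r.add(j)
    rows = []
    for i, d_id in enumerate(denovo.signature_ids):
        if i in assignment:
            j, s = assignment[i]
            rows.append((d_id, reference.signature_ids[j], round(float(s), 6), True))
        else:
            rows.append((d_id, None, float(sim[i].max()) if sim.shape[1] else np.nan, False))
    return pd.DataFrame(rows, columns=["denovo_id", "reference_id", "cosine", "matched"])


def _pruned_nnls(P: np.ndarray, x: np.ndarray, prune_threshold: float) -> np.ndarray:
    """NNLS of x on columns of P, iteratively re-fit after dropping components
    whose relative weight falls below ``prune_threshold``. Returns a weight
    vector over all columns of P (pruned entries zero)."""
    n_total = P.shape[1]
    active = np.arange(n_total)
    w, _ = nnls(P, x)
    while True:
        total = w.sum()
        if total <= 0:
            return np.zeros(n_total)
        keep = (w / total) >= prune_threshold
        if keep.all():
            break
        active = active[keep]
        if active.size == 0:
            return np.zeros(n_total)
        w, _ = nnls(P[:, keep], x)
        P = P[:, keep]
    full = np.zeros(n_total)
    full[active] = w
    return full


def decompose_to_reference(
    profile: np.ndarray, reference: SignatureSet, prune_threshold: float = 0.01
) -> dict[str, float]:
    """Express a profile as a sparse non-negative mixture of reference columns."""
    profile = np.asarray(profile, dtype=float).ravel()
    w = _pruned_nnls(reference.profiles, profile, prune_threshold)
    total = w.sum()
    if total <= 0:
        return {}
    w = w / total
    return {
        sig: float(w[i]) for i, sig in enumerate(reference.signature_ids) if w[i] > 0
    }


def refit_exposures(
    catalog: MutationCatalog, reference: SignatureSet, prune_threshold: float = 0.01
) -> ExposureMatrix:
    """Per-sample NNLS attribution of catalog counts to reference signatures.

    Signatures contributing less than ``prune_threshold`` of a sample's
    burden are zeroed and the remainder refit; absolute exposures are scaled
    so each row sums to the sample's burden. Zero-burden samples yield an
    all-zero row and are flagged.
    """
    if list(catalog.channel_labels) != list(reference.channel_labels):
        raise TypeError("catalog and reference signature channel schemes differ")
    if reference.n_signatures == 0:
        raise ValueError("reference signature set is empty")
    n_samples = len(catalog.sample_ids)
    k = reference.n_signatures
    absolute = np.zeros((n_samples, k))
    relative = np.zeros((n_samples, k))
    flagged = []
    for i, row in enumerate(catalog.counts):
        burden = row.sum()
        if burden == 0:
            flagged.append(catalog.sample_ids[i])
            continue
        w = _pruned_nnls(reference.profiles, row.astype(float), prune_threshold)
        total = w.sum()
        if total <= 0:
            flagged.append(catalog.sample_ids[i])
            continue
        rel = w / total
        relative[i] = rel
        absolute[i] = rel * burden
    return ExposureMatrix(
        list(catalog.sample_ids), list(reference.signature_ids), absolute, relative, flagged
    )
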