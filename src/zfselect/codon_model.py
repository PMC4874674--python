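"""Goldman–Yang codon substitution machinery with F3X4 frequencies.

The state space is the 61 sense codons of the standard genetic code.  Rates
between codons differing at one nucleotide follow the classic pattern
``pi_j * {1, kappa, omega, omega*kappa}`` for (transversion, transition) x
(synonymous, nonsynonymous); multi-nucleotide exchanges are instantaneous-
rate zero.  Equilibrium frequencies come from position-specific nucleotide
counts (F3X4) renormalized over sense codons.  Matrices are scaled so the
expected substitution rate is one per codon — for site-class mixtures the
scaling factor is shared across classes, so branch lengths stay in expected
substitutions per codon averaged over classes.

Likelihoods are computed by Felsenstein pruning with per-site rescaling;
transition probabilities use eigendecomposition of the reversible generator
in the pi^{1/2}-symmetrized basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .seq_io import STANDARD_CODE
from .trees import Tree

__all__ = [
    "CODONS",
    "STOP_CODONS",
    "CODON_INDEX",
    "CODON_AA",
    "MISSING",
    "codons_to_codes",
    "codes_to_codons",
    "f3x4_frequencies",
    "build_rate_matrix",
    "mixture_rate_matrices",
    "mixture_scale_factor",
    "transition_probabilities",
    "TreeIndex",
    "CodonLikelihood",
    "simulate_mixture_alignment",
]

_NT = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
CODONS = tuple(
    a + b + c
    for a in _NT
    for b in _NT
    for c in _NT
    if a + b + c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
CODON_AA = tuple(STANDARD_CODE(c) for c in CODONS)
MISSING = -1

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _pair_structure():
    """Index arrays for all single-nucleotide codon exchanges."""
    src, dst, is_ts, is_nonsyn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            src.append(i)
            dst.append(j)
            is_ts.append(frozenset(diffs[0]) in _TRANSITIONS)
            is_nonsyn.append(CODON_AA[i] != CODON_AA[j])
    return (
        np.array(src),
        np.array(dst),
        np.array(is_ts, dtype=bool),
        np.array(is_nonsyn, dtype=bool),
    )


_SRC, _DST, _IS_TS, _IS_NONSYN = _pair_structure()


def codons_to_codes(seq_codons) -> np.ndarray:
    """Map codon strings to state codes; None/'---'/N-containing -> MISSING."""
    out = np.empty(len(seq_codons), dtype=np.int64)
    for k, codon in enumerate(seq_codons):
        if codon is None or "-" in codon or "N" in codon:
            out[k] = MISSING
        elif codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} has no sense-codon state")
        else:
            out[k] = CODON_INDEX[codon]
    return out


def codes_to_codons(codes) -> list[str]:
    return [CODONS[c] if c != MISSING else "---" for c in codes]


def f3x4_frequencies(codes: np.ndarray) -> np.ndarray:
    """F3X4 codon frequencies from observed codon states.

    ``codes`` is any array of sense-codon codes (MISSING entries ignored).
    A nucleotide absent at some codon position receives a pseudocount of 0.5
    with a warning.  Returns frequencies over the 61 sense codons.
    """
    observed = np.asarray(codes).ravel()
    observed = observed[observed != MISSING]
    if observed.size == 0:
        raise ValueError("no observed codons")
    counts = np.zeros((3, 4))
    for code in observed:
        codon = CODONS[code]
        for pos in range(3):
            counts[pos, _NT.index(codon[pos])] += 1
    if (counts == 0).any():
        warnings.warn("nucleotide absent at some codon position; pseudocount 0.5")
        counts[counts == 0] = 0.5
    nt_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            nt_freq[0, _NT.index(c[0])]
            * nt_freq[1, _NT.index(c[1])]
            * nt_freq[2, _NT.index(c[2])]
            for c in CODONS
        ]
    )
    return pi / pi.sum()


def _unscaled_q(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    q = np.zeros((61, 61))
    rates = pi[_DST] * np.where(_IS_TS, kappa, 1.0) * np.where(_IS_NONSYN, omega, 1.0)
    q[_SRC, _DST] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def build_rate_matrix(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    """Single-class GY94 generator scaled to one expected substitution."""
    q = _unscaled_q(pi, kappa, omega)
    rate = -np.dot(pi, np.diag(q))
    return q / rate


def mixture_scale_factor(pi, kappa, omegas, weights) -> float:
    """Weight-averaged expected rate of the unscaled per-class generators."""
    omegas = np.asarray(omegas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(
        sum(
            wt * -np.dot(pi, np.diag(_unscaled_q(pi, kappa, w)))
            for wt, w in zip(weights, omegas)
        )
    )


def mixture_rate_matrices(pi, kappa, omegas, weights) -> list[np.ndarray]:
    """Per-class generators sharing one scaling factor.

    The common factor is the weight-averaged expected rate, so a unit of
    branch length is one expected substitution per codon averaged over site
    classes (faster-than-average classes keep their faster clocks).
    """
    omegas = np.asarray(omegas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    qs = [_unscaled_q(pi, kappa, w) for w in omegas]
    mean_rate = sum(
        wt * -np.dot(pi, np.diag(q)) for wt, q in zip(weights, qs)
    )
    return [q / mean_rate for q in qs]


def _symmetric_eig(q: np.ndarray, pi: np.ndarray):
    d = np.sqrt(pi)
    b = (q * d[:, None]) / d[None, :]
    lam, u = np.linalg.eigh((b + b.T) / 2)
    left = u.T * d[None, :]          # U^T D^{1/2}
    right = u / d[:, None]           # D^{-1/2} U
    return lam, right, left


def transition_probabilities(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via the symmetrized eigendecomposition."""
    lam, right, left = _symmetric_eig(q, pi)
    p = (right * np.exp(lam * t)[None, :]) @ left
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=1, keepdims=True)


@dataclass
class TreeIndex:
    """Flat postorder arrays for one tree against a fixed taxon order."""

    parent: np.ndarray       # parent node id per node (-1 for root)
    lengths: np.ndarray      # branch length above each node
    postorder: np.ndarray    # node ids, children before parents
    children: list[list[int]]
    leaf_taxon: dict[int, int]  # node id -> row in the alignment
    n_nodes: int

    @classmethod
    def build(cls, tree: Tree, taxa: list[str]) -> "TreeIndex":
        taxon_row = {name: i for i, name in enumerate(taxa)}
        tree_names = tree.leaf_names()
        if sorted(tree_names) != sorted(taxa):
            raise ValueError(
                f"tree leaves {sorted(tree_names)} do not match taxa {sorted(taxa)}"
            )
        parent, lengths, children, leaf_taxon, post = [], [], [], {}, []

        def walk(node, par):
            nid = len(parent)
            parent.append(par)
            lengths.append(node.length)
            children.append([])
            if par >= 0:
                children[par].append(nid)
            if node.is_leaf:
                leaf_taxon[nid] = taxon_row[node.name]
            for ch in node.children:
                walk(ch, nid)
            post.append(nid)

        walk(tree.root, -1)
        return cls(
            parent=np.array(parent),
            lengths=np.array(lengths),
            postorder=np.array(post),
            children=children,
            leaf_taxon=leaf_taxon,
            n_nodes=len(parent),
        )


class CodonLikelihood:
    """Pruning likelihood for one alignment/tree, reusable across parameters.

    Identical alignment columns are collapsed to site patterns internally;
    per-site outputs are expanded back to the original column order.  All
    site classes of a mixture are pruned in one batched pass.
    """

    def __init__(self, codes: np.ndarray, tree: Tree, taxa: list[str],
                 pi: np.ndarray | None = None):
        codes = np.asarray(codes)
        if codes.ndim != 2 or codes.shape[0] != len(taxa):
            raise ValueError("codes must be (n_taxa, n_sites)")
        self.codes = codes
        self.taxa = list(taxa)
        self.n_sites = codes.shape[1]
        self.index = TreeIndex.build(tree, self.taxa)
        self.pi = f3x4_frequencies(codes) if pi is None else np.asarray(pi)
        patterns, self._pattern_of_site, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self._pattern_weight = counts.astype(float)
        self.n_patterns = patterns.shape[1]
        # leaf partials over patterns: indicators, or ones for missing data
        self._leaf_partials = {}
        for nid, row in self.index.leaf_taxon.items():
            part = np.zeros((61, self.n_patterns))
            obs = patterns[row]
            miss = obs == MISSING
            part[:, miss] = 1.0
            cols = np.where(~miss)[0]
            part[obs[cols], cols] = 1.0
            self._leaf_partials[nid] = part

    def set_branch_lengths(self, lengths: np.ndarray) -> None:
        self.index.lengths = np.asarray(lengths, dtype=float)

    def _pattern_logliks(self, qs) -> np.ndarray:
        """(n_classes, n_patterns) log-likelihoods, batched over classes."""
        idx = self.index
        k = len(qs)
        d = np.sqrt(self.pi)
        b = np.stack(qs) * d[None, :, None] / d[None, None, :]
        lam, u = np.linalg.eigh((b + np.swapaxes(b, 1, 2)) / 2)
        right = u / d[None, :, None]                 # (k,61,61)
        left = np.swapaxes(u, 1, 2) * d[None, None, :]
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros((k, self.n_patterns))
        for nid in idx.postorder:
            if not idx.children[nid]:
                partials[nid] = np.broadcast_to(
                    self._leaf_partials[nid], (k, 61, self.n_patterns)
                )
                continue
            acc = np.ones((k, 61, self.n_patterns))
            for ch in idx.children[nid]:
                p = (right * np.exp(lam * idx.lengths[ch])[:, None, :]) @ left
                np.clip(p, 0.0, None, out=p)
                acc *= p @ partials.pop(ch)
            scale = acc.max(axis=1)
            if (scale <= 0).any():
                raise FloatingPointError(
                    f"zero partial likelihood at patterns "
                    f"{np.where((scale <= 0).any(axis=0))[0].tolist()}"
                )
            acc /= scale[:, None, :]
            logscale += np.log(scale)
            partials[nid] = acc
        root = idx.postorder[-1]
        site = np.einsum("i,kis->ks", self.pi, partials[root])
        if not np.all(site > 0):
            raise FloatingPointError("non-positive site likelihood at the root")
        return np.log(site) + logscale

    def class_site_logliks(self, kappa: float, omegas,
                           scale_factor: float | None = None) -> np.ndarray:
        """(n_classes, n_sites) per-site log-likelihoods, one row per omega.

        With ``scale_factor=None`` each row's generator is scaled on its own
        (expected rate one).  Passing the fitted mixture's scale factor keeps
        every row on the branch-length clock of that fit, so faster classes
        keep their faster clocks — required when the rows feed an empirical
        Bayes site classification.
        """
        omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
        if scale_factor is None:
            qs = [build_rate_matrix(self.pi, kappa, w) for w in omegas]
        else:
            qs = [_unscaled_q(self.pi, kappa, w) / scale_factor for w in omegas]
        return self._pattern_logliks(qs)[:, self._pattern_of_site]

    def loglik(self, kappa: float, weights, omegas,
               return_site: bool = False):
        """Mixture log-likelihood: sum_h log sum_k w_k f_h(omega_k)."""
        weights = np.asarray(weights, dtype=float)
        omegas = np.asarray(omegas, dtype=float)
        if weights.shape != omegas.shape:
            raise ValueError("weights and omegas must align")
        if abs(weights.sum() - 1) > 1e-9 or (weights < -1e-12).any():
            raise ValueError("class weights must be a distribution")
        qs = mixture_rate_matrices(self.pi, kappa, omegas, weights)
        ls = self._pattern_logliks(qs)
        keep = weights > 0
        lw = np.full_like(weights, -np.inf)
        lw[keep] = np.log(weights[keep])
        m = (ls + lw[:, None]).max(axis=0)
        pattern = m + np.log(np.exp(ls + lw[:, None] - m[None, :]).sum(axis=0))
        if not np.all(np.isfinite(pattern)):
            bad = int(np.where(~np.isfinite(pattern))[0][0])
            raise FloatingPointError(f"non-finite likelihood at pattern {bad}")
        total = float(pattern @ self._pattern_weight)
        return (total, pattern[self._pattern_of_site]) if return_site else total




def simulate_mixture_alignment(tree: Tree, taxa: list[str], pi: np.ndarray,
                               kappa: float, weights, omegas, n_sites: int,
                               rng: np.random.Generator):
    """Forward-simulate codon states under a GY94 site-class mixture.

    Sites draw a class by weight; a root codon is drawn from pi and evolved
    down the tree with exp(Qt) transition sampling.  Stop codons are never
    emitted (the state space excludes them).  Returns ``(codes, classes)``
    with ``codes`` shaped (n_taxa, n_sites).
    """
    weights = np.asarray(weights, dtype=float)
    omegas = np.asarray(omegas, dtype=float)
    idx = TreeIndex.build(tree, taxa)
    qs = mixture_rate_matrices(pi, kappa, omegas, weights)
    classes = rng.choice(len(weights), size=n_sites, p=weights / weights.sum())
    # transition matrices per (class, node)
    pmats = {}
    for k, q in enumerate(qs):
        lam, right, left = _symmetric_eig(q, pi)
        for nid in range(idx.n_nodes):
            if idx.parent[nid] < 0:
                continue
            p = (right * np.exp(lam * idx.lengths[nid])[None, :]) @ left
            np.clip(p, 0.0, None, out=p)
            pmats[(k, nid)] = p / p.sum(axis=1, keepdims=True)
    states = np.empty((idx.n_nodes, n_sites), dtype=np.int64)
    preorder = idx.postorder[::-1]
    root = preorder[0]
    states[root] = rng.choice(61, size=n_sites, p=pi / pi.sum())
    for nid in preorder[1:]:
        par = idx.parent[nid]
        for k in range(len(qs)):
            sites_k = np.where(classes == k)[0]
            if sites_k.size == 0:
                continue
            p = pmats[(k, nid)]
            u = rng.random(sites_k.size)
            cum = np.cumsum(p[states[par, sites_k]], axis=1)
            states[nid, sites_k] = (u[:, None] > cum).sum(axis=1)
    codes = np.empty((len(taxa), n_sites), dtype=np.int64)
    for nid, row in idx.leaf_taxon.items():
        codes[row] = states[nid]
    return codes, classes
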