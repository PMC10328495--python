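"""Partitioned amino-acid likelihood engine (LG family, +Gamma, +I, +F).

Implements Felsenstein pruning over 20-state amino-acid data with discrete
gamma rate heterogeneity, an invariant-site class and optional observed
(+F) frequencies; per-branch length optimization by round-robin univariate
search; and exhaustive constrained topology search on small taxon sets
(<= 8 taxa, i.e. up to 10,395 unrooted topologies). This is deliberately a
desk-scale engine: it exists so constrained vs unconstrained fits — the
inputs to AICc model comparison — can be produced end-to-end on simulated
data without any external tree-search program.

Conventions: the mixture site likelihood is

    L_site = (1 - p_inv) * (1/C) * sum_k L_site(r_k) + p_inv * pi_x * [constant]

with C equal-probability gamma categories whose rates are slice means (not
medians) and are NOT renormalized by 1/(1 - p_inv). Gaps and the ambiguity
codes B, Z, J, X contribute all-ones partials (missing data). Site ranges in
partition schemes are 0-based half-open.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .treeio import PhyloTree, parse_newick

__all__ = [
    "AMINO_ACIDS",
    "AminoAlignment",
    "SubstitutionModel",
    "Partition",
    "PartitionScheme",
    "lg_model",
    "model_from_spec",
    "read_fasta",
    "write_fasta",
    "parse_partition_file",
    "concatenate_alignments",
    "build_rate_matrix",
    "discrete_gamma",
    "transition_probs",
    "tree_log_likelihood",
    "partitioned_log_likelihood",
    "optimize_branch_lengths",
    "constrained_best_tree",
    "enumerate_topologies",
    "count_free_parameters",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_MISSING_CODES = set("-?.BZJX*")


# ---------------------------------------------------------------------------
# alignment container


class AminoAlignment:
    """An amino-acid alignment: ordered taxa x equal-length residue rows."""

    def __init__(self, taxa, sequences):
        taxa = list(taxa)
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels in alignment")
        if isinstance(sequences, dict):
            sequences = [sequences[t] for t in taxa]
        sequences = [str(s).upper() for s in sequences]
        if len(sequences) != len(taxa):
            raise ValueError("one sequence per taxon required")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self.taxa = taxa
        self.sequences = sequences
        self.length = lengths.pop() if lengths else 0
        codes = np.full((len(taxa), self.length), -1, dtype=np.int8)
        for i, seq in enumerate(sequences):
            for j, ch in enumerate(seq):
                if ch in _AA_INDEX:
                    codes[i, j] = _AA_INDEX[ch]
                elif ch not in _MISSING_CODES:
                    raise ValueError(
                        f"invalid residue {ch!r} at site {j} of {taxa[i]!r}"
                    )
        self.codes = codes

    def __len__(self):
        return self.length

    def row(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def subset_sites(self, start: int, end: int) -> "AminoAlignment":
        return AminoAlignment(self.taxa, [s[start:end] for s in self.sequences])

    def observed_frequencies(self, pseudocount: float = 0.05) -> np.ndarray:
        """Residue frequencies with a 1/20 pseudo-count per absent residue.

        Used by +F models in place of the empirical model frequencies.
        """
        counts = np.zeros(20)
        flat = self.codes[self.codes >= 0]
        for c in flat:
            counts[c] += 1
        counts[counts == 0] = pseudocount
        return counts / counts.sum()


def read_fasta(path) -> AminoAlignment:
    from Bio import SeqIO

    taxa, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id if " " not in rec.description else rec.description)
        seqs.append(str(rec.seq))
    if not taxa:
        raise ValueError(f"no sequences found in {path}")
    return AminoAlignment(taxa, seqs)


def write_fasta(aln: AminoAlignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# substitution model


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible amino-acid model: exchangeabilities s_ij, frequencies pi,
    discrete-gamma shape alpha with C categories, and invariant fraction."""

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_shape: float | None = None
    n_categories: int = 4
    p_invariant: float = 0.0
    name: str = "custom"

    def __post_init__(self):
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (20, 20):
            raise ValueError("exchangeabilities must be 20x20")
        if not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(s < 0) or np.any(np.diag(s) != 0):
            raise ValueError("exchangeabilities must be non-negative, zero diagonal")
        if pi.shape != (20,) or abs(pi.sum() - 1.0) > 1e-8 or np.any(pi <= 0):
            raise ValueError("frequencies must be 20 positive values summing to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if not (0 <= self.p_invariant < 1):
            raise ValueError("p_invariant must be in [0, 1)")
        object.__setattr__(self, "exchangeabilities", s)
        object.__setattr__(self, "frequencies", pi / pi.sum())

    def with_frequencies(self, freqs) -> "SubstitutionModel":
        return SubstitutionModel(
            self.exchangeabilities, np.asarray(freqs, float),
            self.gamma_shape, self.n_categories, self.p_invariant,
            self.name + "+F",
        )

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma(self.gamma_shape, self.n_categories)


def _load_lg():
    text = resources.files("phylohypo.data").joinpath("lg.dat").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    order = lines[0].split()
    s = np.zeros((20, 20))
    for i in range(1, 20):
        vals = [float(x) for x in lines[i].split()]
        for j, v in enumerate(vals):
            s[i, j] = s[j, i] = v
    freqs = np.array([float(x) for x in lines[20].split()])
    # reorder to the module's canonical residue order if needed
    perm = [order.index(aa) for aa in AMINO_ACIDS]
    s = s[np.ix_(perm, perm)]
    freqs = freqs[perm]
    return s, freqs / freqs.sum()


_LG_CACHE = None


def lg_model(
    gamma_shape: float | None = None,
    n_categories: int = 4,
    p_invariant: float = 0.0,
    frequencies=None,
) -> SubstitutionModel:
    """The LG empirical amino-acid model, optionally +Gamma, +I and +F."""
    global _LG_CACHE
    if _LG_CACHE is None:
        _LG_CACHE = _load_lg()
    s, pi = _LG_CACHE
    if frequencies is not None:
        pi = np.asarray(frequencies, dtype=float)
    name = "LG"
    if gamma_shape is not None:
        name += f"+G{n_categories}"
    if p_invariant > 0:
        name += "+I"
    if frequencies is not None:
        name += "+F"
    return SubstitutionModel(s, pi, gamma_shape, n_categories, p_invariant, name)


def model_from_spec(
    spec: str,
    gamma_shape: float = 1.0,
    p_invariant: float = 0.25,
    alignment: AminoAlignment | None = None,
) -> SubstitutionModel:
    """Build a model from a spec string such as ``LG+G4+I`` or ``LG+G4+F``.

    ``gamma_shape`` and ``p_invariant`` supply the numeric values for the +G
    and +I components (this engine does not estimate them); +F takes observed
    frequencies from ``alignment``.
    """
    parts = spec.upper().split("+")
    if parts[0] != "LG":
        raise ValueError(f"unsupported base model {parts[0]!r} (only LG)")
    shape, ncat, pinv, freqs = None, 4, 0.0, None
    for part in parts[1:]:
        m = re.fullmatch(r"G(\d*)", part)
        if m:
            shape = gamma_shape
            if m.group(1):
                ncat = int(m.group(1))
        elif part == "I":
            pinv = p_invariant
        elif part == "F":
            if alignment is None:
                raise ValueError("+F requires an alignment for observed frequencies")
            freqs = alignment.observed_frequencies()
        else:
            raise ValueError(f"unknown model component {part!r} in {spec!r}")
    return lg_model(shape, ncat, pinv, freqs)


# ---------------------------------------------------------------------------
# partitions


@dataclass
class Partition:
    name: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    model: SubstitutionModel | None = None


@dataclass
class PartitionScheme:
    partitions: list

    def __post_init__(self):
        parts = sorted(self.partitions, key=lambda p: p.start)
        covered = 0
        for p in parts:
            if p.start != covered or p.end <= p.start:
                raise ValueError(
                    "partition ranges must be disjoint, in order, and cover "
                    f"the alignment; bad range [{p.start}, {p.end})"
                )
            covered = p.end
        self.partitions = parts

    @property
    def total_length(self) -> int:
        return self.partitions[-1].end

    def assign_models(self, models) -> "PartitionScheme":
        if isinstance(models, SubstitutionModel):
            models = [models] * len(self.partitions)
        if len(models) != len(self.partitions):
            raise ValueError("one model per partition required")
        return PartitionScheme(
            [Partition(p.name, p.start, p.end, m)
             for p, m in zip(self.partitions, models)]
        )

    @classmethod
    def single(cls, length: int, model: SubstitutionModel | None = None,
               name: str = "all") -> "PartitionScheme":
        return cls([Partition(name, 0, length, model)])


def parse_partition_file(text: str) -> PartitionScheme:
    """Parse lines of ``name = start-end`` with 1-based inclusive ranges."""
    parts = []
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        m = re.fullmatch(r"(\S+)\s*=\s*(\d+)\s*-\s*(\d+)", line)
        if not m:
            raise ValueError(f"cannot parse partition line: {line!r}")
        name, lo, hi = m.group(1), int(m.group(2)), int(m.group(3))
        parts.append(Partition(name, lo - 1, hi))
    if not parts:
        raise ValueError("empty partition file")
    return PartitionScheme(parts)


def concatenate_alignments(alignments, names=None):
    """Append alignment blocks site-wise; absent taxa are gap-filled.

    Returns the concatenated alignment and a :class:`PartitionScheme` whose
    ranges record each input block (0-based half-open).
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("no alignment blocks given")
    if names is None:
        names = [f"block{i + 1}" for i in range(len(alignments))]
    taxa = []
    for aln in alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    rows = {t: [] for t in taxa}
    parts, offset = [], 0
    for name, aln in zip(names, alignments):
        for t in taxa:
            rows[t].append(aln.row(t) if t in aln.taxa else "-" * aln.length)
        parts.append(Partition(name, offset, offset + aln.length))
        offset += aln.length
    combined = AminoAlignment(taxa, {t: "".join(rows[t]) for t in taxa})
    return combined, PartitionScheme(parts)


# ---------------------------------------------------------------------------
# rate matrix machinery


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Generator matrix q_ij = s_ij pi_j, rows summing to zero, scaled so the
    expected substitution rate at stationarity is 1."""
    q = model.exchangeabilities * model.frequencies[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -np.dot(model.frequencies, np.diag(q))
    return q / rate


def discrete_gamma(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability gamma slices.

    The gamma has mean 1 (shape = rate = ``shape``); each category's rate is
    the conditional mean of its quantile slice, so the rates average to 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one category")
    if n_categories == 1:
        return np.ones(1)
    probs = np.arange(1, n_categories) / n_categories
    bounds = gamma_dist.ppf(probs, a=shape, scale=1.0 / shape)
    # E[X; X < q] for mean-1 gamma equals the regularized gammainc(shape+1, shape*q)
    cum = np.concatenate([[0.0], gammainc(shape + 1, shape * bounds), [1.0]])
    return n_categories * np.diff(cum)


class _Eigen:
    """Symmetrized eigendecomposition of a reversible rate matrix.

    With D = diag(sqrt(pi)), A = D Q D^-1 is symmetric; P(t) = D^-1 U
    exp(L t) U' D, guaranteeing real eigenvalues and numerically clean
    stochastic matrices.
    """

    def __init__(self, model: SubstitutionModel):
        q = build_rate_matrix(model)
        pi = model.frequencies
        d = np.sqrt(pi)
        a = (q * d[:, None]) / d[None, :]
        a = (a + a.T) / 2.0
        lam, u = np.linalg.eigh(a)
        self.lam = lam
        self.left = u / d[:, None] * 1.0  # D^-1 U
        self.right = (u * d[:, None]).T  # U' D
        self.pi = pi

    def probs(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self.left * np.exp(self.lam * t)[None, :]) @ self.right
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)


def _eigen_for(model: SubstitutionModel) -> _Eigen:
    # memoized on the model instance (frozen dataclass, hence setattr dance)
    eig = getattr(model, "_eigen_cache", None)
    if eig is None:
        eig = _Eigen(model)
        object.__setattr__(model, "_eigen_cache", eig)
    return eig


def transition_probs(model: SubstitutionModel, t: float) -> np.ndarray:
    """Transition probability matrix P(t) = exp(Q t) for the scaled generator."""
    return _eigen_for(model).probs(t)


# ---------------------------------------------------------------------------
# pruning engine


class _TreeGraph:
    """Array view of a tree: undirected adjacency with branch ids."""

    def __init__(self, tree: PhyloTree):
        nodes = list(tree.dendropy_tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.leaf_label = {}
        for i, n in enumerate(nodes):
            if n.is_leaf():
                self.leaf_label[i] = n.taxon.label
        self.adj = [[] for _ in nodes]
        self.blens = []
        self._branch_nodes = []  # dendropy child node per branch
        for n in nodes:
            if n.parent_node is None:
                continue
            u, v = index[id(n.parent_node)], index[id(n)]
            if n.edge.length is None:
                raise ValueError("branch lengths are required for likelihoods")
            b = len(self.blens)
            self.blens.append(float(n.edge.length))
            self._branch_nodes.append(n)
            self.adj[u].append((v, b))
            self.adj[v].append((u, b))
        self.blens = np.array(self.blens)

    def write_back(self) -> None:
        for b, node in enumerate(self._branch_nodes):
            node.edge.length = float(self.blens[b])

    def postorder_from(self, root: int):
        """(node, parent, branch) triples, children before parents."""
        order, stack = [], [(root, -1, -1)]
        while stack:
            node, parent, branch = stack.pop()
            order.append((node, parent, branch))
            for nb, b in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node, b))
        return order[::-1]


class _PartitionData:
    """Compressed site patterns plus model machinery for one partition."""

    def __init__(self, aln: AminoAlignment, taxa_order, model: SubstitutionModel,
                 start: int, end: int):
        if model is None:
            raise ValueError("partition has no substitution model assigned")
        rows = []
        for t in taxa_order:
            if t not in aln.taxa:
                raise ValueError(f"taxon {t!r} missing from alignment")
            rows.append(aln.codes[aln.taxa.index(t), start:end])
        codes = np.vstack(rows)  # (n_taxa, L)
        patterns, inverse, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_taxa, n_pat)
        self.counts = counts.astype(float)
        self.model = model
        self.eigen = _eigen_for(model)
        self.rates = model.category_rates()
        # invariant-class likelihood per pattern: sum of pi over states
        # consistent with every observed residue (gaps allow all states)
        pi = model.frequencies
        n_pat = patterns.shape[1]
        inv = np.zeros(n_pat)
        for j in range(n_pat):
            col = patterns[:, j]
            obs = set(col[col >= 0].tolist())
            if len(obs) == 0:
                inv[j] = 1.0
            elif len(obs) == 1:
                inv[j] = pi[obs.pop()]
        self.inv_lik = inv
        # leaf partials per taxon row: (n_pat, 20)
        self.leaf_partials = []
        eye = np.eye(20)
        ones = np.ones(20)
        for i in range(patterns.shape[0]):
            lp = np.empty((n_pat, 20))
            for j in range(n_pat):
                c = patterns[i, j]
                lp[j] = ones if c < 0 else eye[c]
            self.leaf_partials.append(lp)


class LikelihoodEngine:
    """Felsenstein pruning with per-node scaling over a partitioned alignment.

    Branch lengths live in the engine's tree graph; ``log_likelihood`` and
    the branch optimizer act on that shared state.
    """

    def __init__(self, tree: PhyloTree, aln: AminoAlignment,
                 scheme: PartitionScheme):
        if scheme.total_length != aln.length:
            raise ValueError(
                f"partition scheme covers {scheme.total_length} sites but the "
                f"alignment has {aln.length}"
            )
        self.tree = tree.copy()
        self.graph = _TreeGraph(self.tree)
        taxa_order = [self.graph.leaf_label[i]
                      for i in sorted(self.graph.leaf_label)]
        self.parts = [
            _PartitionData(aln, taxa_order, p.model, p.start, p.end)
            for p in scheme.partitions
        ]
        self._leaf_row = {}
        for rank, i in enumerate(sorted(self.graph.leaf_label)):
            self._leaf_row[i] = rank

    # -- core pruning ------------------------------------------------------

    def _partials(self, part: _PartitionData, root: int):
        """Per-category scaled partials oriented away from ``root``.

        Returns (partials, logscale) dicts keyed by node: arrays of shape
        (n_cat, n_pat, 20) and (n_cat, n_pat).
        """
        ncat = len(part.rates)
        n_pat = part.patterns.shape[1]
        partials, logscale = {}, {}
        order = self.graph.postorder_from(root)
        children = {node: [] for node, _, _ in order}
        for node, parent, branch in order:
            if parent >= 0:
                children[parent].append((node, branch))
        for node, parent, branch in order:
            kids = children[node]
            if not kids:
                row = self._leaf_row[node]
                lp = np.broadcast_to(
                    part.leaf_partials[row], (ncat, n_pat, 20)
                ).copy()
                partials[node] = lp
                logscale[node] = np.zeros((ncat, n_pat))
                continue
            acc = np.ones((ncat, n_pat, 20))
            ls = np.zeros((ncat, n_pat))
            for child, b in kids:
                t = self.graph.blens[b]
                for k, r in enumerate(part.rates):
                    p = part.eigen.probs(t * r)
                    acc[k] *= partials[child][k] @ p.T
                ls += logscale[child]
            if node in self._leaf_row:
                # traversal rooted at a leaf: keep its observed-state indicator
                acc *= part.leaf_partials[self._leaf_row[node]][None]
            mx = acc.max(axis=2)
            mx[mx == 0.0] = 1.0
            acc /= mx[:, :, None]
            partials[node] = acc
            logscale[node] = ls + np.log(mx)
        return partials, logscale, children

    def _site_loglik(self, part, cat_log, n_pat):
        """Combine per-category pattern log-likelihoods with the invariant class."""
        model = part.model
        p_inv = model.p_invariant
        ncat = cat_log.shape[0]
        mx = cat_log.max(axis=0)
        mx = np.where(np.isfinite(mx), mx, 0.0)
        var = np.exp(cat_log - mx[None, :]).sum(axis=0) / ncat
        with np.errstate(divide="ignore"):
            log_var = math.log1p(-p_inv) + mx + np.log(var)
            if p_inv <= 0:
                return log_var
            log_inv = np.log(p_inv * part.inv_lik)
        return np.logaddexp(log_var, log_inv)

    def _part_loglik(self, part: _PartitionData) -> float:
        root = 0
        partials, logscale, _ = self._partials(part, root)
        pi = part.model.frequencies
        lik = partials[root] @ pi  # (ncat, n_pat)
        with np.errstate(divide="ignore"):
            cat_log = np.log(lik) + logscale[root]
        site = self._site_loglik(part, cat_log, part.patterns.shape[1])
        return float(np.dot(site, part.counts))

    def log_likelihood(self) -> float:
        return sum(self._part_loglik(p) for p in self.parts)

    # -- branch-length optimization ---------------------------------------

    def _edge_loglik_fn(self, parent: int, child: int, branch: int):
        """Cheap logL(t) for one branch, partials frozen at current lengths."""
        per_part = []
        for part in self.parts:
            partials, logscale, children = self._partials(part, parent)
            ncat = len(part.rates)
            n_pat = part.patterns.shape[1]
            # side of `parent`: product of messages from its other neighbours
            acc = np.ones((ncat, n_pat, 20))
            ls = np.zeros((ncat, n_pat))
            for other, b in children[parent]:
                if other == child:
                    continue
                t = self.graph.blens[b]
                for k, r in enumerate(part.rates):
                    p = part.eigen.probs(t * r)
                    acc[k] *= partials[other][k] @ p.T
                ls += logscale[other]
            if parent in self._leaf_row:
                acc = acc * part.leaf_partials[self._leaf_row[parent]][None]
            a_side = acc * part.model.frequencies[None, None, :]
            down = partials[child]
            ls_total = ls + logscale[child]
            per_part.append((part, a_side, down, ls_total))

        def loglik(t: float) -> float:
            total = 0.0
            for part, a_side, down, ls_total in per_part:
                ncat = a_side.shape[0]
                lik = np.empty(a_side.shape[:2])
                for k, r in enumerate(part.rates):
                    p = part.eigen.probs(t * r)
                    lik[k] = np.einsum("pj,pj->p", a_side[k], down[k] @ p.T)
                with np.errstate(divide="ignore"):
                    cat_log = np.log(lik) + ls_total
                site = self._site_loglik(part, cat_log, lik.shape[1])
                total += float(np.dot(site, part.counts))
            return total

        return loglik

    def optimize_branch_lengths(
        self, tol: float = 1e-6, max_sweeps: int = 20,
        max_branch_length: float = 30.0, xatol: float = 1e-6,
    ) -> float:
        """Round-robin bounded univariate optimization of every branch.

        Each branch is optimized with partials recomputed at the current
        lengths, so the total log-likelihood never decreases. Iterates until
        the improvement over a full sweep drops below ``tol``.
        """
        current = self.log_likelihood()
        if not math.isfinite(current):
            raise ValueError("non-finite log-likelihood at starting lengths")
        n_branches = len(self.graph.blens)
        branch_ends = {}
        for node in range(self.graph.n_nodes):
            for nb, b in self.graph.adj[node]:
                branch_ends[b] = (node, nb)
        for _ in range(max_sweeps):
            before = current
            for b in range(n_branches):
                parent, child = branch_ends[b]
                f = self._edge_loglik_fn(parent, child, b)
                t0 = self.graph.blens[b]
                res = minimize_scalar(
                    lambda t: -f(t),
                    bounds=(1e-9, max_branch_length),
                    method="bounded",
                    options={"xatol": xatol},
                )
                if -res.fun > f(t0):
                    self.graph.blens[b] = float(res.x)
                    current = -res.fun
            if current - before < tol:
                break
        self.graph.write_back()
        return current

    def tree_with_lengths(self) -> PhyloTree:
        self.graph.write_back()
        return self.tree.copy()


# ---------------------------------------------------------------------------
# public likelihood API


def tree_log_likelihood(tree: PhyloTree, aln: AminoAlignment,
                        model: SubstitutionModel) -> float:
    """Log-likelihood of the alignment on the tree under one model."""
    scheme = PartitionScheme.single(aln.length, model)
    return LikelihoodEngine(tree, aln, scheme).log_likelihood()


def partitioned_log_likelihood(tree: PhyloTree, aln: AminoAlignment,
                               scheme: PartitionScheme) -> float:
    """Sum of per-partition log-likelihoods with shared topology and lengths."""
    return LikelihoodEngine(tree, aln, scheme).log_likelihood()


def optimize_branch_lengths(tree: PhyloTree, aln: AminoAlignment,
                            scheme: PartitionScheme, tol: float = 1e-6,
                            **kwargs):
    """Optimize all branch lengths; returns (tree with new lengths, logL)."""
    engine = LikelihoodEngine(tree, aln, scheme)
    logl = engine.optimize_branch_lengths(tol=tol, **kwargs)
    return engine.tree_with_lengths(), logl


def count_free_parameters(n_taxa: int, scheme: PartitionScheme) -> int:
    """Parameter count K for AIC: 2n-3 branch lengths (linked across
    partitions) plus per-partition model parameters (alpha for +G, p_inv for
    +I, 19 free frequencies for +F)."""
    k = 2 * n_taxa - 3
    for p in scheme.partitions:
        m = p.model
        if m is None:
            continue
        if m.gamma_shape is not None:
            k += 1
        if m.p_invariant > 0:
            k += 1
        if "+F" in m.name:
            k += 19
    return k


# ---------------------------------------------------------------------------
# exhaustive topology search


def enumerate_topologies(taxa):
    """Yield every unrooted binary topology on ``taxa`` as nested tuples.

    The representation is a basal trifurcation (3-tuple at the top); a
    2-tuple elsewhere is an internal node. Counts follow (2n-5)!!:
    3 topologies at n=4, 15 at n=5, ..., 10,395 at n=8.
    """
    taxa = sorted(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def insert_everywhere(subtree, leaf):
        # yields all trees obtained by attaching `leaf` on an edge in `subtree`
        yield (subtree, leaf)
        if isinstance(subtree, tuple):
            left, right = subtree
            for new_left in insert_everywhere(left, leaf):
                yield (new_left, right)
            for new_right in insert_everywhere(right, leaf):
                yield (left, new_right)

    def build(k):
        if k == 3:
            yield (taxa[0], taxa[1], taxa[2])
            return
        for smaller in build(k - 1):
            a, b, c = smaller
            for new_a in insert_everywhere(a, taxa[k - 1]):
                yield (new_a, b, c)
            for new_b in insert_everywhere(b, taxa[k - 1]):
                yield (a, new_b, c)
            for new_c in insert_everywhere(c, taxa[k - 1]):
                yield (a, b, new_c)

    yield from build(len(taxa))


def _topology_splits(top):
    """Non-trivial splits (as frozensets, both orientations) of a nested-tuple
    unrooted topology, plus the full taxon set."""
    splits = set()

    def leafset(sub):
        if isinstance(sub, tuple):
            s = frozenset()
            for child in sub:
                cs = leafset(child)
                splits.add(cs)
                s = s | cs
            return s
        return frozenset([sub])

    all_taxa = leafset(top)
    out = set()
    for s in splits:
        if 2 <= len(s) <= len(all_taxa) - 2:
            out.add(s)
            out.add(all_taxa - s)
    return out, all_taxa


def _hypothesis_on_splits(hyp, splits, all_taxa) -> bool:
    def mono(ts):
        ts = frozenset(ts)
        return len(ts) == 1 or ts == all_taxa or ts in splits

    if hyp.predicate_kind == "monophyly":
        return mono(hyp.focal_sets[0])
    if hyp.predicate_kind == "negative_monophyly":
        return not mono(hyp.focal_sets[0])
    a, b = hyp.focal_sets
    return mono(a) and mono(b) and mono(a | b)


def _topology_newick(top, blen: float) -> str:
    def render(sub):
        if isinstance(sub, tuple):
            inner = ",".join(render(c) for c in sub)
            return f"({inner}):{blen}"
        label = sub
        if any(ch in label for ch in " ():,;'"):
            label = "'" + label.replace("'", "''") + "'"
        return f"{label}:{blen}"

    a, b, c = top
    return f"({render(a)},{render(b)},{render(c)});"


def constrained_best_tree(
    aln: AminoAlignment,
    scheme: PartitionScheme,
    constraint=None,
    negative: bool = False,
    initial_length: float = 0.1,
    tol: float = 1e-4,
    max_sweeps: int = 4,
    xatol: float = 1e-4,
):
    """Exhaustive ML topology search under a topological constraint.

    Enumerates every unrooted binary topology on the alignment's taxa,
    keeps those satisfying ``constraint`` (or violating it when
    ``negative=True``), optimizes branch lengths on each and returns the
    (tree, logL) maximizing the likelihood; ties go to the first topology in
    enumeration order. Limited to 8 taxa (10,395 topologies).
    """
    taxa = sorted(aln.taxa)
    if len(taxa) > 8:
        raise ValueError(
            f"exhaustive search limited to 8 taxa, got {len(taxa)}"
        )
    best = None
    n_considered = 0
    for top in enumerate_topologies(taxa):
        if constraint is not None:
            splits, all_taxa = _topology_splits(top)
            ok = _hypothesis_on_splits(constraint, splits, all_taxa)
            if negative:
                ok = not ok
            if not ok:
                continue
        n_considered += 1
        tree = parse_newick(_topology_newick(top, initial_length))
        engine = LikelihoodEngine(tree, aln, scheme)
        logl = engine.optimize_branch_lengths(
            tol=tol, max_sweeps=max_sweeps, xatol=xatol
        )
        if best is None or logl > best[1]:
            best = (engine.tree_with_lengths(), logl)
    if best is None:
        raise ValueError("constraint is unsatisfiable on this taxon set")
    return best
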