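"""Birth-death simulators and synthetic fixtures.

Everything the analysis consumes can be generated here: ultrametric
family-level trees from constant-rate or shift-bearing birth-death
processes, per-family richness (either by collapsing a species-level tree
at a time slice or by drawing from the stem-age geometric law), and
taxonomic evaluation counts splitting a true richness into
accepted/rejected/unevaluated names.

All generators draw from a single ``numpy.random.Generator`` seeded per
call; identical seeds give byte-identical Newick output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .richness import FamilyCounts
from .shifts import BDParams
from .tree_model import CladeRecord, DatedTree, enumerate_clades

__all__ = [
    "ShiftSpec",
    "ShiftedTreeResult",
    "WholeTreeExtinctionError",
    "collapse_to_families",
    "null_clade_table",
    "seedplant_clade_table",
    "seedplant_marginal_clade_table",
    "plant_shifts",
    "sample_family_richness",
    "simulate_bd_tree",
    "simulate_taxonomic_counts",
    "simulate_unresolved_yule_tree",
    "simulate_unresolved_yule_tree_with_shift",
]


@dataclass(frozen=True)
class ShiftSpec:
    """A planted diversification-rate shift.

    At ``time`` (My after the process starts) one alive lineage switches to
    λ·multiplier; its descendants inherit the new rates, nested later shifts
    taking precedence.  ``new_epsilon`` (optional) resets μ/λ; otherwise the
    old ratio is kept.  The lineage is picked uniformly at random unless
    ``lineage`` gives a deterministic index into the alive set (sorted by
    lineage id) or ``within_shift`` restricts the choice to descendants of an
    earlier shift in the same list (for explicitly nested shifts).
    """

    time: float
    multiplier: float
    new_epsilon: Optional[float] = None
    lineage: Optional[int] = None
    within_shift: Optional[int] = None

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("shift multiplier must be > 0")
        if self.new_epsilon is not None and not 0 <= self.new_epsilon < 1:
            raise ValueError("new_epsilon must lie in [0, 1)")


class _Lineage:
    __slots__ = ("id", "parent", "start", "end", "lam", "mu", "children", "fate")

    def __init__(self, id_, parent, start, lam, mu):
        self.id = id_
        self.parent = parent
        self.start = start
        self.end: Optional[float] = None
        self.lam = lam
        self.mu = mu
        self.children: List[int] = []
        self.fate: Optional[str] = None  # "birth" | "death" | "shift" | None (extant)


class WholeTreeExtinctionError(RuntimeError):
    """All simulated lineages died before the stopping condition."""


def _simulate_once(lam, mu, shifts, n_tips, max_age, rng):
    lineages = [_Lineage(0, None, 0.0, lam, mu)]
    alive = [0]
    pending = sorted(range(len(shifts)), key=lambda i: shifts[i].time)
    shift_lineage: Dict[int, int] = {}
    t = 0.0
    if n_tips is not None and n_tips == 1:
        return lineages, 0.0, shift_lineage
    while alive:
        rates = np.array([lineages[i].lam + lineages[i].mu for i in alive])
        total = rates.sum()
        dt = rng.exponential(1.0 / total)
        t_next = t + dt
        if n_tips is not None and len(alive) == n_tips:
            # stop just before the next event so no tip branch has zero length
            t = t_next if max_age is None else min(t_next, max_age)
            break
        if pending and shifts[pending[0]].time <= t_next:
            si = pending.pop(0)
            spec = shifts[si]
            if max_age is not None and spec.time >= max_age:
                continue
            t = spec.time
            pool = sorted(alive)
            if spec.within_shift is not None:
                anc = shift_lineage.get(spec.within_shift)
                if anc is not None:
                    desc = [i for i in pool if _descends(lineages, i, anc)]
                    pool = desc or pool
            if spec.lineage is not None:
                li = pool[spec.lineage % len(pool)]
            else:
                li = pool[rng.integers(len(pool))]
            old = lineages[li]
            # terminate at the shift so every lineage has constant rates
            old.end = t
            old.fate = "shift"
            new_lam = old.lam * spec.multiplier
            eps = spec.new_epsilon if spec.new_epsilon is not None else (
                old.mu / old.lam if old.lam > 0 else 0.0
            )
            child = _Lineage(len(lineages), li, t, new_lam, new_lam * eps)
            old.children = [child.id]
            lineages.append(child)
            alive[alive.index(li)] = child.id
            shift_lineage[si] = child.id
            continue
        if max_age is not None and t_next >= max_age:
            t = max_age
            break
        t = t_next
        j = rng.choice(len(alive), p=rates / total)
        li = alive[j]
        lin = lineages[li]
        if rng.random() < lin.lam / (lin.lam + lin.mu):
            lin.end = t
            lin.fate = "birth"
            for _ in range(2):
                ch = _Lineage(len(lineages), li, t, lin.lam, lin.mu)
                lin.children.append(ch.id)
                lineages.append(ch)
            alive[j] = lin.children[0]
            alive.append(lin.children[1])
        else:
            lin.end = t
            lin.fate = "death"
            alive[j] = alive[-1]
            alive.pop()
    if not alive:
        raise WholeTreeExtinctionError
    return lineages, t, shift_lineage


def _descends(lineages, i, anc) -> bool:
    while i is not None:
        if i == anc:
            return True
        i = lineages[i].parent
    return False


def _build_trees(lineages, T):
    """(complete, reconstructed) dendropy trees; extant tips end at T."""

    def end_of(lin):
        return lin.end if lin.end is not None else T

    has_extant = [False] * len(lineages)
    for lin in reversed(lineages):
        if lin.fate is None:
            has_extant[lin.id] = True
        if lin.parent is not None and has_extant[lin.id]:
            has_extant[lin.parent] = True

    def make(lin_id, keep_only_extant):
        lin = lineages[lin_id]
        node = dendropy.Node()
        node.edge.length = end_of(lin) - lin.start
        kids = lin.children
        if keep_only_extant:
            kids = [c for c in kids if has_extant[c]]
        if not kids:
            node.label = f"L{lin.id:05d}"
        for c in kids:
            node.add_child(make(c, keep_only_extant))
        return node

    def finish(root_node):
        t = dendropy.Tree()
        t.seed_node = root_node
        t.is_rooted = True
        t.suppress_unifurcations()
        for lf in t.leaf_node_iter():
            tx = t.taxon_namespace.new_taxon(label=lf.label)
            lf.taxon = tx
        return t

    complete = finish(make(0, keep_only_extant=False))
    reconstructed = finish(make(0, keep_only_extant=True))
    return complete, reconstructed


def simulate_bd_tree(
    lam: float,
    mu: float = 0.0,
    *,
    n_tips: Optional[int] = None,
    max_age: Optional[float] = None,
    seed: int = 0,
    retry_cap: int = 100,
) -> Tuple[DatedTree, DatedTree]:
    """Constant-rate birth-death simulation from a single stem lineage.

    Exactly one of ``n_tips`` (stop at the first moment that many lineages
    are alive) or ``max_age`` must be given.  Returns the complete tree
    (extinct tips included, not ultrametric) and the reconstructed
    extant-only ultrametric tree.  Whole-tree extinction is retried up to
    ``retry_cap`` times and then raised.
    """
    res = plant_shifts(lam, mu, [], n_tips=n_tips, max_age=max_age,
                       seed=seed, retry_cap=retry_cap)
    return res.complete, res.reconstructed


@dataclass
class ShiftedTreeResult:
    complete: DatedTree
    reconstructed: DatedTree
    rate_map: Dict[str, Tuple[float, float]]  # clade id -> (λ, μ) governing it
    shift_clades: List[Optional[str]]         # per shift; None if no extant trace


def plant_shifts(
    lam: float,
    mu: float,
    shifts: Sequence[ShiftSpec],
    *,
    n_tips: Optional[int] = None,
    max_age: Optional[float] = None,
    seed: int = 0,
    retry_cap: int = 100,
) -> ShiftedTreeResult:
    """Simulate a birth-death tree with planted rate shifts.

    Returns the trees plus the true branch → (λ, μ) map of the reconstructed
    tree (tipward-most rates win on merged branches, so nested shifts govern
    their subtrees) and, per shift, the reconstructed clade id it produced.
    """
    if lam <= mu or mu < 0:
        raise ValueError("need λ > μ >= 0")
    if (n_tips is None) == (max_age is None):
        raise ValueError("give exactly one of n_tips or max_age")
    if n_tips is not None and n_tips < 1:
        raise ValueError("n_tips must be >= 1")
    rng = np.random.default_rng(seed)
    for attempt in range(retry_cap + 1):
        try:
            lineages, T, shift_lineage = _simulate_once(
                lam, mu, list(shifts), n_tips, max_age, rng
            )
            if sum(1 for lin in lineages if lin.fate is None) < 2:
                raise WholeTreeExtinctionError  # a 1-tip survivor is no tree
            break
        except WholeTreeExtinctionError:
            if attempt == retry_cap:
                raise WholeTreeExtinctionError(
                    f"whole tree went (effectively) extinct in {retry_cap + 1} "
                    "consecutive attempts; raise the retry cap or the net rate"
                ) from None
    complete_dp, recon_dp = _build_trees(lineages, T)
    complete = DatedTree(complete_dp, require_ultrametric=False)
    reconstructed = DatedTree(recon_dp)

    # clade of each lineage in the reconstructed tree = its extant tip set
    extant_tips: Dict[int, set] = {}
    for lin in reversed(lineages):
        tips = set()
        if lin.fate is None:
            tips.add(f"L{lin.id:05d}")
        for c in lin.children:
            tips |= extant_tips.get(c, set())
        extant_tips[lin.id] = tips

    def clade_of(tips: set) -> Optional[str]:
        if not tips:
            return None
        return min(tips) if len(tips) == 1 else f"{min(tips)}+{len(tips)}"

    rate_map: Dict[str, Tuple[float, float]] = {}
    for lin in lineages:  # preorder by construction: deeper overwrites
        cid = clade_of(extant_tips[lin.id])
        if cid is not None:
            rate_map[cid] = (lin.lam, lin.mu)
    shift_clades = [
        clade_of(extant_tips[shift_lineage[i]]) if i in shift_lineage else None
        for i in range(len(shifts))
    ]
    return ShiftedTreeResult(complete, reconstructed, rate_map, shift_clades)


def collapse_to_families(
    tree: DatedTree,
    cutoff: float,
) -> Tuple[DatedTree, Dict[str, int]]:
    """Cut an ultrametric species tree at ``cutoff`` My into family tips.

    Each lineage crossing the cutoff becomes one family whose richness is its
    extant species count and whose stem age (top of its subtending branch) is
    preserved.  Total richness is conserved.  Family labels are
    ``fam_<alphabetically first member species>``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if cutoff >= tree.height:
        raise ValueError(
            f"cutoff {cutoff} My is at or above the root age {tree.height:.6g} My"
        )
    richness: Dict[str, int] = {}

    def build(node) -> dendropy.Node:
        out = dendropy.Node()
        out.edge.length = node.edge.length if node.parent_node is not None else None
        if tree.crown_age(node) <= cutoff:
            members = tree.tip_set(node)
            label = f"fam_{min(members)}"
            richness[label] = len(members)
            out.label = label
            # tip spans from its stem straight to the present
            out.edge.length = tree.stem_age(node)
            return out
        for ch in node.child_nodes():
            out.add_child(build(ch))
        return out

    root = build(tree.dendropy_tree.seed_node)
    fam = dendropy.Tree()
    fam.seed_node = root
    fam.is_rooted = True
    for lf in fam.leaf_node_iter():
        lf.taxon = fam.taxon_namespace.new_taxon(label=lf.label)
    return DatedTree(fam), richness


def simulate_taxonomic_counts(
    S_true: int,
    synonym_rate: float = 0.5,
    eval_fraction: float = 0.6,
    seed: int = 0,
    family: str = "fam",
) -> FamilyCounts:
    """Emulate taxonomic evaluation of a family with ``S_true`` real species.

    Poisson(S_true·synonym_rate) synonymous names are added to the S_true
    valid ones; each name is independently evaluated with probability
    ``eval_fraction`` and, if evaluated, labeled by its true status.
    """
    if S_true < 1 or int(S_true) != S_true:
        raise ValueError("S_true must be an integer >= 1")
    if synonym_rate < 0:
        raise ValueError("synonym_rate must be >= 0")
    if not 0 <= eval_fraction <= 1:
        raise ValueError("eval_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_syn = int(rng.poisson(S_true * synonym_rate))
    S_A = int(rng.binomial(S_true, eval_fraction))
    S_R = int(rng.binomial(n_syn, eval_fraction))
    S_U = (S_true - S_A) + (n_syn - S_R)
    return FamilyCounts(family, S_A, S_R, S_U)


def sample_family_richness(
    tree: DatedTree,
    params: BDParams,
    seed: int = 0,
    rate_map: Optional[Dict[str, Tuple[float, float]]] = None,
) -> Dict[str, int]:
    """Draw per-tip richness from the stem-age geometric law.

    Conditional on survival, a clade of stem age s under (λ, μ) holds
    N ~ Geometric(1−β) species with β = λ(1−e^{−rs})/(λ−μe^{−rs}).  A
    ``rate_map`` (e.g. from :func:`plant_shifts`) overrides the global
    parameters per tip, so planted shifts show in the richnesses too.
    """
    rng = np.random.default_rng(seed)
    out: Dict[str, int] = {}
    for node in tree.dendropy_tree.leaf_node_iter():
        label = tree.clade_id(node)
        lam, mu = params.lam, params.mu
        if rate_map and label in rate_map:
            lam, mu = rate_map[label]
        r = lam - mu
        s = tree.stem_age(node)
        x = math.exp(-r * s)
        beta = lam * (1.0 - x) / (lam - mu * x)
        out[label] = int(rng.geometric(1.0 - beta))
    return out


# -- exact sampler for the unresolved-family likelihood -------------------


class _TreeTooBig(RuntimeError):
    pass


def _draw_unresolved_lineage(rng, age, rate, family_prob, counter, max_tips):
    """One lineage born at ``age``: a family tip or a backbone split."""
    counter[0] += 1
    if counter[0] > max_tips:
        raise _TreeTooBig
    node = dendropy.Node()
    if rng.random() < family_prob:
        node.label = ("F", int(rng.geometric(math.exp(-rate * age))))
        node.edge.length = age
        return node
    wait = rng.exponential(1.0 / rate)
    if wait >= age:
        node.label = ("F", 1)  # reached the present without splitting
        node.edge.length = age
        return node
    x = age - wait
    node.edge.length = age - x
    for _ in range(2):
        node.add_child(
            _draw_unresolved_lineage(rng, x, rate, family_prob, counter, max_tips)
        )
    return node


def _finish_family_tree(root) -> Tuple[DatedTree, Dict[str, int]]:
    tree = dendropy.Tree()
    tree.seed_node = root
    tree.is_rooted = True
    richness: Dict[str, int] = {}
    for i, lf in enumerate(tree.leaf_node_iter()):
        label = f"F{i:04d}"
        richness[label] = lf.label[1]
        lf.label = label
        lf.taxon = tree.taxon_namespace.new_taxon(label=label)
    return DatedTree(tree), richness


def simulate_unresolved_yule_tree(
    lam: float,
    *,
    family_prob: float = 0.5,
    root_age: float = 60.0,
    seed: int = 0,
    min_tips: int = 4,
    max_tips: int = 300,
    retry_cap: int = 1000,
) -> Tuple[DatedTree, Dict[str, int]]:
    """Sample a family tree + richnesses exactly from the fitted model.

    The unresolved-clade likelihood describes a two-level pure-birth
    process: backbone lineages give birth at rate λ, and each lineage is,
    at its birth, either a family stem (probability ``family_prob``) whose
    richness then grows as a Yule process from its stem age (so it is
    geometric at the present), or a backbone lineage that will split
    again.  A backbone lineage reaching the present unsplit is a monotypic
    family.  Sampling forward from this process makes maximum-likelihood
    recovery tests well-specified; drawing richness on top of an ordinary
    n-tip simulation would double-count the birth-free pendant branches.

    ``family_prob`` (> 0.5 keeps the tree finite with margin) controls the
    expected family count; λ only scales the ages.  Draws outside
    [min_tips, max_tips] tips are rejected and retried, all seeded.
    """
    if not 0 < family_prob < 1:
        raise ValueError("family_prob must lie in (0, 1)")
    if root_age <= 0 or lam <= 0:
        raise ValueError("need lam > 0 and root_age > 0")
    rng = np.random.default_rng(seed)
    for _ in range(retry_cap + 1):
        counter = [0]
        try:
            root = dendropy.Node()
            for _ in range(2):
                root.add_child(
                    _draw_unresolved_lineage(
                        rng, root_age, lam, family_prob, counter, max_tips * 4
                    )
                )
        except _TreeTooBig:
            continue
        n = sum(1 for _ in root.leaf_iter())
        if min_tips <= n <= max_tips:
            return _finish_family_tree(root)
    raise RuntimeError(
        f"no draw within [{min_tips}, {max_tips}] tips in {retry_cap + 1} attempts"
    )


def simulate_unresolved_yule_tree_with_shift(
    lam: float,
    multiplier: float,
    *,
    family_prob: float = 0.5,
    root_age: float = 60.0,
    seed: int = 0,
    min_tips: int = 30,
    max_tips: int = 150,
    min_shift_tips: int = 20,
    max_shift_tips: int = 60,
    stem_age_range: Tuple[float, float] = (0.3, 0.65),
    retry_cap: int = 2000,
) -> Tuple[DatedTree, Dict[str, int], str]:
    """A family tree with one planted λ-multiplier shift on a subclade.

    A no-shift draw is taken first; a backbone branch with stem age inside
    ``stem_age_range`` (fractions of the root age) is chosen at random and
    its whole subtree regenerated from that stem age at rate λ·multiplier —
    forward sampling of the shifted two-level model.  Draws are rejected
    until the shifted clade has [min_shift_tips, max_shift_tips] families
    and the tree [min_tips, max_tips].  Returns (tree, richness, clade id
    of the true shift branch).
    """
    rng = np.random.default_rng(seed)
    lo, hi = (root_age * f for f in stem_age_range)
    for _ in range(retry_cap + 1):
        counter = [0]
        try:
            root = dendropy.Node()
            for _ in range(2):
                root.add_child(
                    _draw_unresolved_lineage(
                        rng, root_age, lam, family_prob, counter, max_tips * 4
                    )
                )
        except _TreeTooBig:
            continue
        # candidate shift branches: internal, stem age within the window
        ages: Dict[int, float] = {}
        for nd in _postorder(root):
            ages[id(nd)] = 0.0 if nd.is_leaf() else max(
                ages[id(ch)] + ch.edge.length for ch in nd.child_nodes()
            )
        candidates = [
            nd
            for nd in _postorder(root)
            if nd.parent_node is not None
            and not nd.is_leaf()
            and lo <= ages[id(nd.parent_node)] <= hi
        ]
        if not candidates:
            continue
        target = candidates[rng.integers(len(candidates))]
        stem = ages[id(target.parent_node)]
        sub_counter = [0]
        try:
            new_sub = _draw_unresolved_lineage(
                rng, stem, lam * multiplier, family_prob, sub_counter, max_tips * 4
            )
        except _TreeTooBig:
            continue
        n_sub = sum(1 for _ in new_sub.leaf_iter())
        if not min_shift_tips <= n_sub <= max_shift_tips:
            continue
        parent = target.parent_node
        parent.remove_child(target)
        parent.add_child(new_sub)
        n = sum(1 for _ in root.leaf_iter())
        if not min_tips <= n <= max_tips:
            continue
        tree, richness = _finish_family_tree(root)
        # labels were just rewritten by _finish_family_tree
        shift_tips = {lf.label for lf in new_sub.leaf_iter()}
        cid = min(shift_tips) if len(shift_tips) == 1 else f"{min(shift_tips)}+{len(shift_tips)}"
        return tree, richness, cid
    raise RuntimeError(f"no acceptable shifted draw in {retry_cap + 1} attempts")


def _postorder(root):
    stack, out = [root], []
    while stack:
        nd = stack.pop()
        out.append(nd)
        stack.extend(nd.child_nodes())
    return reversed(out)


# -- preset clade tables -------------------------------------------------


def seedplant_clade_table(
    seed: int = 0,
    n_families: int = 425,
    lam: float = 0.02,
    meanlog: float = 4.0,
    sdlog: float = 2.2,
) -> List[CladeRecord]:
    """A full-scale synthetic clade table (default 425 families, 849 clades).

    The family tree is a Yule tree (λ = 0.02/My gives a ≈300 My root, the
    depth of a seed-plant family phylogeny) and family richness is
    log-normal with a heavy right tail (meanlog 4.0, sdlog 2.2: median ≈55
    species, total ≈2–4·10⁵), floored at 1 so monotypic families occur.
    """
    rng = np.random.default_rng(seed)
    _, tree = simulate_bd_tree(lam, 0.0, n_tips=n_families,
                               seed=int(rng.integers(2**31)))
    rich = {
        label: max(1.0, float(np.round(v)))
        for label, v in zip(tree.tip_labels, rng.lognormal(meanlog, sdlog, n_families))
    }
    return enumerate_clades(tree, rich)


# per-window clade counts of the published family-level age-richness table
# (20–30 … 90–100 My); the only per-clade age distribution in print
_WINDOW_COUNTS = np.array([48, 82, 80, 106, 76, 60, 42, 46], dtype=float)


def seedplant_marginal_clade_table(
    seed: int = 0,
    n_clades: int = 849,
    monotypic_fraction: float = 0.06,
    lns_mu: float = 6.3,
    lns_sd: float = 2.7,
    lns_max: float = 12.82,
) -> List[CladeRecord]:
    """Clade (age, richness) pairs drawn from published marginals only.

    Stem ages follow the printed per-window clade counts of the 20–100 My
    regression table (uniform within each 10-My window); ln S mixes a
    monotypic mass (≈6%, the share of monospecific seed-plant families)
    with a normal truncated to [0, 12.82] whose parameters reproduce the
    printed mean ln S ≈ 5.94.  No tree structure is implied (tip sets are
    disjoint singletons); the table is meant for analyses that consume
    only (stem age, S) pairs, such as the rate–richness permutation null.
    """
    rng = np.random.default_rng(seed)
    w = _WINDOW_COUNTS / _WINDOW_COUNTS.sum()
    lo = rng.choice(np.arange(20.0, 100.0, 10.0), size=n_clades, p=w)
    ages = lo + rng.uniform(0.0, 10.0, n_clades)
    lns = rng.normal(lns_mu, lns_sd, n_clades).clip(0.0, lns_max)
    lns[rng.random(n_clades) < monotypic_fraction] = 0.0
    return [
        CladeRecord(
            clade_id=f"C{i:04d}",
            tip_families=frozenset([f"C{i:04d}"]),
            stem_age=float(ages[i]),
            crown_age=0.0,
            richness=float(np.exp(lns[i])),
            ln_richness=float(lns[i]),
        )
        for i in range(n_clades)
    ]


def null_clade_table(
    seed: int = 0,
    n_families: int = 150,
    lam: float = 0.05,
    meanlog: float = 3.0,
    sdlog: float = 1.5,
) -> List[CladeRecord]:
    """Clade table with richness independent of age (a regression null).

    Ages and nesting structure come from a simulated Yule family tree, but
    every clade's richness is redrawn iid log-normal — deliberately *not*
    summed over subtrees, because subtree sums grow with clade size and
    hence age, which would reintroduce the signal under test.
    """
    rng = np.random.default_rng(seed)
    _, tree = simulate_bd_tree(lam, 0.0, n_tips=n_families,
                               seed=int(rng.integers(2**31)))
    records = []
    for node in tree.nodes():
        s = max(1.0, float(np.round(rng.lognormal(meanlog, sdlog))))
        records.append(
            CladeRecord(
                clade_id=tree.clade_id(node),
                tip_families=tree.tip_set(node),
                stem_age=tree.stem_age(node),
                crown_age=tree.crown_age(node),
                richness=s,
                ln_richness=math.log(s),
            )
        )
    return records
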