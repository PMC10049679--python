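"""Constrained random generation of clonal phylogenies and CCF trajectories.

A phylogeny is a rooted tree of tumor clones (the root's parent is the
germline, clone id 0 = normal cells) plus a matrix of cancer cell
fractions (CCFs, percent) per clone and time point. CCFs are CUMULATIVE:
a clone's CCF counts every cell carrying its variants, including all of
its descendants. Five constraints define validity:

1. A child clone cannot exceed its parent at any time point.
2. The CCFs of the direct children of a clone cannot sum to more than
   the parent's CCF; clones descending directly from the germline
   cannot sum to more than 100%.
3. An eradicated clone cannot re-appear: once a clone's CCF hits zero
   it stays zero at all later time points.
4. Every clone reaches the detection threshold ``minth`` at >=1 time point.
5. Every pair of clones is separated by >= ``mindist`` CCF at >=1 time point.

Generation is rejection sampling: per new clone up to 100 CCF draws, and
up to 700 whole-simulation restarts (including a fresh founding clone)
before giving up.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .params import SimulationParams

GERMLINE = 0

#: per-clone CCF redraws before the whole simulation is restarted
MAX_CLONE_ATTEMPTS = 100
#: whole-simulation restarts before declaring the parameters infeasible
MAX_RESTARTS = 700

_EPS = 1e-9


class PhylogenyError(RuntimeError):
    pass


class InfeasiblePhylogenyError(PhylogenyError):
    """No feasible phylogeny found within the retry budget."""


@dataclass
class Violation:
    """One violated phylogeny constraint, naming constraint, clone(s) and
    time point (``None`` when the constraint is not time-point specific)."""

    constraint: str
    clones: tuple[int, ...]
    timepoint: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.message


@dataclass
class Phylogeny:
    """Clone tree plus cumulative CCF trajectories.

    Clones are numbered 1..n in order of appearance; row ``i-1`` of
    ``ccf`` belongs to clone ``i``. ``parents[c]`` is the parent clone id
    (0 for the germline root). ``variants_per_clone[c]`` is the number of
    variants (SNVs + CNVs) first acquired in clone ``c``.
    """

    parents: dict[int, int]
    ccf: np.ndarray  # (n_clones, n_timepoints), percent in [0, 100]
    variants_per_clone: dict[int, int] = field(default_factory=dict)

    @property
    def n_clones(self) -> int:
        return self.ccf.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.ccf.shape[1]

    @property
    def clones(self) -> list[int]:
        return sorted(self.parents)

    def children(self, clone: int) -> list[int]:
        return [c for c, p in self.parents.items() if p == clone]

    def clone_ccf(self, clone: int) -> np.ndarray:
        """CCF trajectory of one clone (germline pins 100 at all times)."""
        if clone == GERMLINE:
            return np.full(self.n_timepoints, 100.0)
        return self.ccf[clone - 1]

    def ancestors(self, clone: int) -> set[int]:
        """Strict ancestors of ``clone``, germline excluded."""
        out: set[int] = set()
        c = self.parents[clone]
        while c != GERMLINE:
            out.add(c)
            c = self.parents[c]
        return out

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if clone ``a`` is a strict ancestor of clone ``b``."""
        return a in self.ancestors(b) or a == GERMLINE != b

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            parents=dict(self.parents),
            ccf=self.ccf.copy(),
            variants_per_clone=dict(self.variants_per_clone),
        )


# ---------------------------------------------------------------------------
# validation

def validate_phylogeny(phylo: Phylogeny, params: SimulationParams) -> list[Violation]:
    """Check every phylogeny constraint; return an empty list iff all hold.

    Raises ``PhylogenyError`` on structural inconsistency (dimension
    mismatch, unreachable clones, cycles) rather than reporting it as a
    violation.
    """
    n = phylo.n_clones
    clones = phylo.clones
    if sorted(phylo.parents) != list(range(1, n + 1)):
        raise PhylogenyError(
            f"parent map covers clones {sorted(phylo.parents)} but CCF matrix has {n} rows"
        )
    # reachability from germline doubles as the acyclicity check
    for c in clones:
        seen = {c}
        p = phylo.parents[c]
        while p != GERMLINE:
            if p in seen or p not in phylo.parents:
                raise PhylogenyError(f"clone {c} is not reachable from the germline (cycle or dangling parent {p})")
            seen.add(p)
            p = phylo.parents[p]

    v: list[Violation] = []
    ntp = phylo.n_timepoints
    minth = params.detection_threshold
    mindist = params.min_clonal_distance

    for c in clones:
        cc = phylo.clone_ccf(c)
        if np.any(cc < -_EPS) or np.any(cc > 100 + _EPS):
            v.append(Violation("ccf_out_of_range", (c,), None,
                               f"clone {c} has CCF outside [0, 100]"))
        pc = phylo.clone_ccf(phylo.parents[c])
        for t in range(ntp):
            if cc[t] > pc[t] + _EPS:
                v.append(Violation(
                    "child_exceeds_parent", (c, phylo.parents[c]), t,
                    f"child exceeds parent: clone {c} CCF {cc[t]:.1f} > "
                    f"parent {phylo.parents[c]} CCF {pc[t]:.1f} at time point {t}"))
    for parent in [GERMLINE] + clones:
        kids = phylo.children(parent)
        if len(kids) < 2 and parent != GERMLINE:
            continue
        total = np.sum([phylo.clone_ccf(k) for k in kids], axis=0) if kids else np.zeros(ntp)
        bound = phylo.clone_ccf(parent)
        for t in range(ntp):
            if total[t] > bound[t] + _EPS:
                name = ("independent_sum_exceeds_total" if parent == GERMLINE
                        else "children_sum_exceeds_parent")
                v.append(Violation(
                    name, tuple(kids), t,
                    f"children of {'germline' if parent == GERMLINE else f'clone {parent}'} "
                    f"sum to {total[t]:.1f} > {bound[t]:.1f} at time point {t}"))
    for c in clones:
        cc = phylo.clone_ccf(c)
        dead = False
        for t in range(ntp):
            if dead and cc[t] > _EPS:
                v.append(Violation(
                    "eradicated_clone_reappears", (c,), t,
                    f"eradicated clone re-appears: clone {c} CCF {cc[t]:.1f} at "
                    f"time point {t} after reaching zero"))
            if cc[t] <= _EPS:
                dead = True
        if np.max(cc) < minth - _EPS:
            v.append(Violation(
                "below_detection_threshold", (c,), None,
                f"clone {c} never reaches the detection threshold {minth:g}"))
    for i, a in enumerate(clones):
        for b in clones[i + 1:]:
            delta = np.max(np.abs(phylo.clone_ccf(a) - phylo.clone_ccf(b)))
            if delta < mindist - _EPS:
                v.append(Violation(
                    "clonal_distance", (a, b), None,
                    f"clones {a} and {b} never differ by >= {mindist:g} CCF "
                    f"(max difference {delta:.1f})"))
    if phylo.variants_per_clone:
        counts = phylo.variants_per_clone
        if sorted(counts) != clones:
            raise PhylogenyError("variants_per_clone does not cover exactly the simulated clones")
        for c in clones:
            if counts[c] < 1:
                v.append(Violation(
                    "variant_count", (c,), None,
                    f"clone {c} carries {counts[c]} variants; every clone needs >= 1"))
    return v


# ---------------------------------------------------------------------------
# generation

def _round_down(x: float) -> float:
    """Truncate to 1 decimal so rounding can never push a draw above its
    feasibility bound."""
    return np.floor(x * 10.0 + _EPS) / 10.0


#: CCF window (percent) of the near-parent proposal mode
_NEAR_PARENT_SPREAD = 25.0


def _draw_separated_value(rng: np.random.Generator, hi: float,
                          others: list[float], mindist: float,
                          lo: float = 0.0) -> float | None:
    """Uniform draw from [lo, hi] minus the union of +-mindist bands
    around every existing clone's CCF at this time point; None if empty."""
    segs = [(lo, hi)] if hi > lo else []
    for o in others:
        nxt = []
        for a, b in segs:
            ba, bb = o - mindist, o + mindist
            if bb <= a or ba >= b:
                nxt.append((a, b))
                continue
            if ba > a:
                nxt.append((a, ba))
            if bb < b:
                nxt.append((bb, b))
        segs = nxt
    total = sum(b - a for a, b in segs)
    if total <= 0:
        return None
    x = rng.uniform(0.0, total)
    for a, b in segs:
        if x <= b - a:
            v = _round_down(a + x)
            return v if v >= a - _EPS else a
        x -= b - a
    return _round_down(segs[-1][1])  # pragma: no cover - float guard


def _draw_clone_ccf(rng: np.random.Generator, upper: np.ndarray,
                    existing: list[np.ndarray], minth: float,
                    mindist: float, constructive: bool) -> np.ndarray | None:
    """Propose one clone's trajectory below the feasible bound ``upper``,
    on a 0.1 CCF grid, forcing zeros to persist (eradication).

    Free proposals mix a uniform draw on [0, bound] (diverse subclones,
    eradications) with an incremental draw within 25 CCF of the bound (a
    clone sweeping through most of its parent, as in stepwise linear
    evolution); a pure uniform proposal decays geometrically along a chain
    and cannot reach 8-10 clone phylogenies within the retry budget.
    When ``constructive`` (the later attempts for a clone), one random
    time point is additionally drawn directly from the region separated
    by >= mindist from every existing clone and, where possible, above
    the detection threshold — so in crowded phylogenies the pairwise-
    distance constraint is satisfied by construction rather than luck.
    Candidates are still accepted only if every constraint holds.
    """
    ntp = upper.shape[0]
    out = np.zeros(ntp)
    near_parent = rng.random() < 0.5
    tstar = int(rng.integers(ntp)) if constructive else -1
    for t in range(ntp):
        if t > 0 and out[t - 1] <= _EPS:
            out[t] = 0.0
            continue
        hi = max(upper[t], 0.0)
        if hi <= 0:
            if t == tstar and existing:
                return None  # cannot separate at the chosen time point
            out[t] = 0.0
        elif t == tstar:
            others = [row[t] for row in existing]
            v = _draw_separated_value(rng, hi, others, mindist, lo=min(minth, hi))
            if v is None:
                v = _draw_separated_value(rng, hi, others, mindist)
            if v is None:
                return None
            out[t] = v
        elif near_parent:
            out[t] = _round_down(hi - rng.uniform(0.0, min(hi, _NEAR_PARENT_SPREAD)))
        else:
            out[t] = _round_down(rng.uniform(0.0, hi))
    return out


def _satisfies_local(ccf_new: np.ndarray, existing: list[np.ndarray],
                     minth: float, mindist: float) -> bool:
    if np.max(ccf_new) < minth - _EPS:
        return False
    for other in existing:
        if np.max(np.abs(ccf_new - other)) < mindist - _EPS:
            return False
    return True


def _pick_parent(rng: np.random.Generator, model: str, i: int,
                 existing: list[int]) -> int:
    """Parent for clone i (1-based). Clone 1 always descends from germline;
    the topology of clones 2 and 3 is fixed by the model; later clones
    grow linearly or branch on a fair coin."""
    if i == 1:
        return GERMLINE
    if model == "linear":
        return existing[-1]
    if model == "branched_dependent":
        if i in (2, 3):
            return 1
        if rng.random() < 0.5:
            return existing[-1]
        return int(rng.choice(existing))
    # branched_independent
    if i == 2:
        return GERMLINE
    if rng.random() < 0.5:
        return existing[-1]
    return GERMLINE


def simulate_phylogeny(params: SimulationParams,
                       rng: np.random.Generator | None = None) -> Phylogeny:
    """Generate a random phylogeny satisfying every constraint.

    Raises
    ------
    PhylogenyError
        If a branched model is requested with fewer than 3 clones
        (a branch needs at least 3 clones), or if no feasible phylogeny
        is found after 700 restarts.
    """
    if params.model != "linear" and params.n_clones < 3:
        raise PhylogenyError(
            f"invalid model for n_clones: {params.model} requires >= 3 clones, "
            f"got {params.n_clones}")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    nc, ntp = params.n_clones, params.n_timepoints
    minth, mindist = params.detection_threshold, params.min_clonal_distance

    for _restart in range(MAX_RESTARTS):
        parents: dict[int, int] = {}
        rows: list[np.ndarray] = []
        ok = True
        for i in range(1, nc + 1):
            parent = _pick_parent(rng, params.model, i, list(range(1, i)))
            parents[i] = parent
            # feasible upper bound: parent's CCF minus the CCFs already
            # granted to the parent's other children
            parent_ccf = (np.full(ntp, 100.0) if parent == GERMLINE
                          else rows[parent - 1])
            sibling_sum = np.zeros(ntp)
            for c, p in parents.items():
                if p == parent and c != i:
                    sibling_sum += rows[c - 1]
            upper = parent_ccf - sibling_sum
            for attempt in range(MAX_CLONE_ATTEMPTS):
                cand = _draw_clone_ccf(rng, upper, rows, minth, mindist,
                                       constructive=attempt >= MAX_CLONE_ATTEMPTS // 2)
                if cand is not None and _satisfies_local(cand, rows, minth, mindist):
                    rows.append(cand)
                    break
            else:
                ok = False
            if not ok:
                break
        if ok:
            phylo = Phylogeny(parents=parents, ccf=np.vstack(rows))
            phylo.variants_per_clone = assign_variant_counts(params, rng)
            # belt-and-braces: the constructive sampler should always pass
            if validate_phylogeny(phylo, params):
                continue
            return phylo
    raise InfeasiblePhylogenyError(
        f"no feasible phylogeny after {MAX_RESTARTS} restarts "
        f"(model={params.model}, n_clones={nc}, n_timepoints={ntp}, "
        f"minth={minth}, mindist={mindist})")


def assign_variant_counts(params: SimulationParams,
                          rng: np.random.Generator) -> dict[int, int]:
    """One variant per clone, the remaining ``n_variants - n_clones`` split
    uniformly at random over the clones."""
    if params.n_variants < params.n_clones:
        raise PhylogenyError(
            f"n_variants={params.n_variants} < n_clones={params.n_clones}")
    counts = {c: 1 for c in range(1, params.n_clones + 1)}
    surplus = params.n_variants - params.n_clones
    for c in rng.integers(1, params.n_clones + 1, size=surplus):
        counts[int(c)] += 1
    return counts


# ---------------------------------------------------------------------------
# fine-tuning

@dataclass
class PhylogenyEdits:
    """A batch of clonal-level edits, applied atomically.

    ``set_ccf`` entries are (clone, timepoint, value); ``set_parent``
    entries are (clone, new_parent); ``set_variant_count`` entries are
    (clone, count); ``add_clone`` entries are (parent, ccf trajectory,
    n_variants) and append the next clone id; ``delete_clone`` removes
    leaf clones; ``add_timepoint`` entries are (index, per-clone CCF
    vector) inserting a column; ``delete_timepoint`` removes columns.
    """

    set_ccf: tuple[tuple[int, int, float], ...] = ()
    set_parent: tuple[tuple[int, int], ...] = ()
    set_variant_count: tuple[tuple[int, int], ...] = ()
    add_clone: tuple[tuple[int, tuple[float, ...], int], ...] = ()
    delete_clone: tuple[int, ...] = ()
    add_timepoint: tuple[tuple[int, tuple[float, ...]], ...] = ()
    delete_timepoint: tuple[int, ...] = ()


class EditRejectedError(PhylogenyError):
    """An edit would violate a phylogeny constraint; nothing was applied."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__("edit rejected: " + "; ".join(str(v) for v in violations))


def edit_phylogeny(phylo: Phylogeny, edits: PhylogenyEdits,
                   params: SimulationParams) -> Phylogeny:
    """Apply ``edits`` to a copy and return it, but only if the edited
    phylogeny passes :func:`validate_phylogeny`; otherwise raise
    :class:`EditRejectedError` carrying the named violations and leave the
    input untouched."""
    out = phylo.copy()

    for clone, parent in edits.set_parent:
        if clone not in out.parents:
            raise PhylogenyError(f"set_parent: unknown clone {clone}")
        out.parents[clone] = parent
    for clone, count in edits.set_variant_count:
        if clone not in out.variants_per_clone:
            raise PhylogenyError(f"set_variant_count: unknown clone {clone}")
        out.variants_per_clone[clone] = count
    for clone, t, value in edits.set_ccf:
        if clone not in out.parents:
            raise PhylogenyError(f"set_ccf: unknown clone {clone}")
        out.ccf[clone - 1, t] = value
    for index, column in edits.add_timepoint:
        col = np.asarray(column, dtype=float).reshape(out.n_clones, 1)
        out.ccf = np.hstack([out.ccf[:, :index], col, out.ccf[:, index:]])
    for index in sorted(edits.delete_timepoint, reverse=True):
        out.ccf = np.delete(out.ccf, index, axis=1)
    for parent, traj, nvar in edits.add_clone:
        new_id = out.n_clones + 1
        out.parents[new_id] = parent
        out.ccf = np.vstack([out.ccf, np.asarray(traj, dtype=float)])
        out.variants_per_clone[new_id] = nvar
    for clone in sorted(edits.delete_clone, reverse=True):
        if out.children(clone):
            raise PhylogenyError(f"delete_clone: clone {clone} has children")
        if clone != out.n_clones:
            raise PhylogenyError(
                f"delete_clone: only the highest-numbered clone can be removed "
                f"(got {clone}, have {out.n_clones})")
        del out.parents[clone]
        out.variants_per_clone.pop(clone, None)
        out.ccf = np.delete(out.ccf, clone - 1, axis=0)

    if out.ccf.shape[1] == 0 or out.ccf.shape[0] == 0:
        raise PhylogenyError("edit would leave an empty phylogeny")
    violations = validate_phylogeny(out, params)
    if violations:
        raise EditRejectedError(violations)
    return out
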