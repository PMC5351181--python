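"""Binary-encoded metaheuristics that jointly select a feature subset and the
random-forest parameters (ensemble size ``nTree`` and per-node feature count
``kappa``) by minimising the forest's out-of-bag error.

Chromosome layout: 9 bits for ``nTree`` (1..500), ``bit_length(M)`` bits for
``kappa``, then one mask bit per feature.  A solution is valid when
``1 <= nTree <= 500``, the mask selects at least one feature, and
``1 <= kappa <= popcount(mask)``.  Invalid draws are never silently
repaired during decoding; the optimizers maintain validity as a loop
invariant by redrawing the offending block (bounded retries, then a
targeted uniform repair).

The objective value ``f`` is the per-tree-average OOB error for binary
problems and the aggregate-vote OOB misclassification rate for multiclass
problems; the maximised fitness is ``F = 1 / max(f, 1e-6)``.  The forest
seed is held fixed within an optimizer run (common random numbers) so that
fitness comparisons between chromosomes are paired.

Three engines are provided — roulette-selection genetic algorithm, binary
particle swarm (sigmoid transfer, velocity clamp), and artificial fish swarm
(swarm/follow/prey over a Hamming-ball neighbourhood) — plus sklearn-style
estimators wrapping each around :class:`~imbforest.forest.RandomForest`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .forest import RandomForest

__all__ = [
    "NTREE_BITS",
    "NTREE_MAX",
    "BitCodec",
    "BitSolution",
    "OptimizerTrace",
    "OptimizerParams",
    "random_valid_solution",
    "make_forest_objective",
    "ga_optimize",
    "pso_optimize",
    "afsa_optimize",
    "GARandomForest",
    "PSORandomForest",
    "AFSARandomForest",
    "OPTIMIZERS",
]

NTREE_BITS = 9           # 2**9 = 512 covers the whole 1..500 range
NTREE_MAX = 500
EPS_FITNESS = 1e-6


@dataclass
class BitSolution:
    """A chromosome plus its decoded view and cached objective value."""

    bits: np.ndarray
    n_tree: int
    kappa: int
    mask: np.ndarray            # boolean, length M
    f: float = None             # cached objective (minimised)

    @property
    def fitness(self) -> float:
        return 1.0 / max(self.f, EPS_FITNESS)

    def key(self) -> bytes:
        return self.bits.tobytes()


@dataclass
class OptimizerTrace:
    """Per-generation record of the running best."""

    best_f: list = field(default_factory=list)
    best_bits: list = field(default_factory=list)
    evaluations: int = 0
    best: BitSolution = None

    def update(self, sol: BitSolution):
        if self.best is None or sol.f < self.best.f:
            self.best = sol

    def close_generation(self):
        self.best_f.append(self.best.f)
        self.best_bits.append(self.best.bits.copy())


@dataclass
class OptimizerParams:
    """Shared and per-method metaheuristic settings."""

    popsize: int = 5
    maxgen: int = 20
    # GA
    pc: float = 0.6
    pm: float = 0.1
    # PSO; velocities start uniform in [-v_init, v_init] and are unclamped
    # thereafter (inertia 0.5 bounds them at (c1+c2)/(1-w) = 6 anyway);
    # v_clamp may impose a hard bound when set
    c1: float = 1.5
    c2: float = 1.5
    w: float = 0.5
    v_init: float = 0.5
    v_clamp: float = None
    # AFSA
    visual: int = 3
    try_number: int = 5
    delta: float = 0.618


class BitCodec:
    """Encode/decode (nTree, kappa, feature mask) <-> fixed-length bits."""

    def __init__(self, n_features: int):
        if n_features < 1:
            raise ValueError("need at least one feature")
        self.m = int(n_features)
        self.kappa_bits = self.m.bit_length()
        self.n_bits = NTREE_BITS + self.kappa_bits + self.m

    # -- primitives ------------------------------------------------------
    @staticmethod
    def _to_bits(value, width):
        return np.array([(value >> (width - 1 - i)) & 1 for i in range(width)],
                        dtype=np.uint8)

    @staticmethod
    def _to_int(bits):
        out = 0
        for b in bits:
            out = (out << 1) | int(b)
        return out

    # -- public API ------------------------------------------------------
    def encode(self, n_tree, kappa, mask) -> BitSolution:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.m,):
            raise ValueError("mask length must equal the feature count")
        sol = BitSolution(
            np.concatenate([
                self._to_bits(int(n_tree), NTREE_BITS),
                self._to_bits(int(kappa), self.kappa_bits),
                mask.astype(np.uint8),
            ]),
            int(n_tree), int(kappa), mask,
        )
        ok, reason = self.check(sol)
        if not ok:
            raise ValueError(f"invalid solution: {reason}")
        return sol

    def decode(self, bits) -> BitSolution:
        bits = np.asarray(bits, dtype=np.uint8)
        if bits.shape != (self.n_bits,):
            raise ValueError("bit string has the wrong length")
        n_tree = self._to_int(bits[:NTREE_BITS])
        kappa = self._to_int(bits[NTREE_BITS:NTREE_BITS + self.kappa_bits])
        mask = bits[NTREE_BITS + self.kappa_bits:].astype(bool)
        return BitSolution(bits.copy(), n_tree, kappa, mask)

    def check(self, sol: BitSolution):
        """(is_valid, reason) without repairing anything."""
        if not (1 <= sol.n_tree <= NTREE_MAX):
            return False, f"nTree={sol.n_tree} outside [1, {NTREE_MAX}]"
        pc = int(sol.mask.sum())
        if pc < 1:
            return False, "empty feature mask"
        if not (1 <= sol.kappa <= pc):
            return False, f"kappa={sol.kappa} outside [1, popcount={pc}]"
        return True, ""

    def is_valid(self, bits) -> bool:
        return self.check(self.decode(bits))[0]

    # -- validity maintenance -------------------------------------------
    def repair(self, bits, rng) -> np.ndarray:
        """Targeted uniform repair: redraw each invalid block uniformly over
        its legal range (used only after bounded redraw attempts fail)."""
        sol = self.decode(bits)
        bits = sol.bits.copy()
        if not (1 <= sol.n_tree <= NTREE_MAX):
            bits[:NTREE_BITS] = self._to_bits(int(rng.randint(1, NTREE_MAX + 1)),
                                              NTREE_BITS)
        mask = bits[NTREE_BITS + self.kappa_bits:]
        if mask.sum() < 1:
            mask[rng.randint(self.m)] = 1
        pc = int(mask.sum())
        sol = self.decode(bits)
        if not (1 <= sol.kappa <= pc):
            bits[NTREE_BITS:NTREE_BITS + self.kappa_bits] = self._to_bits(
                int(rng.randint(1, pc + 1)), self.kappa_bits)
        return bits

    def block_slices(self):
        a = NTREE_BITS
        b = NTREE_BITS + self.kappa_bits
        return {"ntree": slice(0, a), "kappa": slice(a, b),
                "mask": slice(b, self.n_bits)}

    def ensure_valid(self, bits, rng, redraw=None, tries=20) -> np.ndarray:
        """Redraw the offending block (via ``redraw(slice)->bits`` or a
        uniform coin-flip default) until valid, then fall back to
        :meth:`repair`."""
        blocks = self.block_slices()
        bits = np.asarray(bits, dtype=np.uint8).copy()
        for _ in range(tries):
            sol = self.decode(bits)
            ok, reason = self.check(sol)
            if ok:
                return bits
            if "nTree" in reason:
                sl = blocks["ntree"]
            elif "mask" in reason:
                sl = blocks["mask"]
            else:
                sl = blocks["kappa"]
            if redraw is not None:
                bits[sl] = redraw(sl)
            else:
                bits[sl] = (rng.uniform(size=sl.stop - sl.start) < 0.5
                            ).astype(np.uint8)
        return self.repair(bits, rng)


def random_valid_solution(codec: BitCodec, rng, max_tries=200) -> BitSolution:
    """Rejection-sample uniform bit strings until valid (bounded retries,
    then targeted repair)."""
    for _ in range(max_tries):
        bits = (rng.uniform(size=codec.n_bits) < 0.5).astype(np.uint8)
        sol = codec.decode(bits)
        if codec.check(sol)[0]:
            return sol
    return codec.decode(codec.repair(bits, rng))


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def make_forest_objective(X, y, max_depth=20, min_leaf=1, forest_seed=0,
                          cache=None):
    """Objective ``f(sol)``: train a forest on the masked features with the
    chromosome's (nTree, kappa) and return its OOB error (per-tree average
    for binary labels, aggregate-vote misclassification for multiclass).

    Results are cached per bit string; the forest seed is fixed so repeated
    evaluations are deterministic and comparisons between chromosomes are
    paired.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    binary = len(np.unique(y)) == 2
    if cache is None:
        cache = {}

    def objective(sol: BitSolution) -> float:
        key = sol.key()
        if key in cache:
            return cache[key]
        cols = np.flatnonzero(sol.mask)
        rf = RandomForest(n_trees=sol.n_tree, kappa=sol.kappa,
                          max_depth=max_depth, min_leaf=min_leaf,
                          random_state=forest_seed)
        rf.fit(np.ascontiguousarray(X[:, cols]), y)
        f = rf.oob_error_ if binary else rf.oob_error_aggregate_
        cache[key] = f
        return f

    objective.cache = cache
    return objective


def _evaluate(sol, objective, trace):
    if sol.f is None:
        sol.f = float(objective(sol))
        trace.evaluations += 1
    trace.update(sol)
    return sol


def _init_population(codec, rng, objective, trace, popsize):
    pop = []
    for _ in range(popsize):
        sol = random_valid_solution(codec, rng)
        pop.append(_evaluate(sol, objective, trace))
    return pop


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def _roulette(fits, rng):
    p = fits / fits.sum()
    return int(rng.choice(len(fits), p=p))


def _single_point_crossover(codec, a, b, rng, tries=20):
    """Cross at a uniformly chosen position where the parents differ; retry
    with another differing position until both offspring are valid.  Parents
    with no differing position (or no valid cut) pass through unchanged."""
    diff = np.flatnonzero(a != b)
    if len(diff) == 0:
        return a.copy(), b.copy()
    for _ in range(tries):
        cut = int(diff[rng.randint(len(diff))])
        c1 = np.concatenate([a[:cut], b[cut:]])
        c2 = np.concatenate([b[:cut], a[cut:]])
        if codec.is_valid(c1) and codec.is_valid(c2):
            return c1, c2
    return a.copy(), b.copy()


def _point_mutation(codec, bits, rng, pm, tries=20):
    """Bit-flip mutation: each position switches 0 and 1 independently with
    probability ``pm``; the draw is regenerated until the mutant is valid
    (bounded tries, then a no-op)."""
    for _ in range(tries):
        flips = rng.uniform(size=len(bits)) < pm
        if not flips.any():
            return bits.copy()
        out = bits.copy()
        out[flips] ^= 1
        if codec.is_valid(out):
            return out
    return bits.copy()


def ga_optimize(objective, codec: BitCodec, params: OptimizerParams = None,
                seed=0) -> OptimizerTrace:
    """Roulette selection, single-point crossover at a differing position,
    per-bit flip mutation at rate ``pm``; generational replacement with
    one-elite preservation and the best-so-far recorded each generation."""
    params = params or OptimizerParams()
    if params.popsize < 2:
        raise ValueError("popsize must be >= 2")
    rng = np.random.RandomState(seed)
    trace = OptimizerTrace()
    pop = _init_population(codec, rng, objective, trace, params.popsize)
    for _ in range(params.maxgen):
        fits = np.array([s.fitness for s in pop])
        nxt = []
        while len(nxt) < params.popsize:
            pa = pop[_roulette(fits, rng)]
            pb = pop[_roulette(fits, rng)]
            ca, cb = pa.bits.copy(), pb.bits.copy()
            if rng.uniform() < params.pc:
                ca, cb = _single_point_crossover(codec, ca, cb, rng)
            for child in (ca, cb):
                if len(nxt) >= params.popsize:
                    break
                child = _point_mutation(codec, child, rng, params.pm)
                nxt.append(_evaluate(codec.decode(child), objective, trace))
        # elitism: the running optimum survives into the next generation
        worst = max(range(len(nxt)), key=lambda i: nxt[i].f)
        if trace.best.f < nxt[worst].f:
            nxt[worst] = trace.best
        pop = nxt
        trace.close_generation()
    return trace


# ---------------------------------------------------------------------------
# Binary particle swarm
# ---------------------------------------------------------------------------

def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def pso_optimize(objective, codec: BitCodec, params: OptimizerParams = None,
                 seed=0) -> OptimizerTrace:
    """Binary PSO: per-bit real velocities with inertia ``w`` and cognitive /
    social pulls ``c1``/``c2`` (per-dimension uniform draws); each bit is
    set to 1 with probability sigmoid(velocity).  Velocities start uniform
    in ``[-v_init, v_init]``; with inertia below 1 the dynamics keep them
    within ``(c1+c2)/(1-w)``, so no hard clamp is applied unless ``v_clamp``
    is set.  Invalid positions redraw the offending block from the same
    sigmoid probabilities."""
    params = params or OptimizerParams()
    if params.popsize < 2:
        raise ValueError("popsize must be >= 2")
    rng = np.random.RandomState(seed)
    trace = OptimizerTrace()
    pop = _init_population(codec, rng, objective, trace, params.popsize)
    x = np.array([s.bits for s in pop], dtype=float)
    v = rng.uniform(-params.v_init, params.v_init,
                    size=(params.popsize, codec.n_bits))
    pbest = [s for s in pop]
    gbest = min(pop, key=lambda s: s.f)
    for _ in range(params.maxgen):
        for k in range(params.popsize):
            r1 = rng.uniform(size=codec.n_bits)
            r2 = rng.uniform(size=codec.n_bits)
            v[k] = (params.w * v[k]
                    + params.c1 * r1 * (pbest[k].bits - x[k])
                    + params.c2 * r2 * (gbest.bits - x[k]))
            if params.v_clamp is not None:
                np.clip(v[k], -params.v_clamp, params.v_clamp, out=v[k])
            prob = _sigmoid(v[k])
            bits = (rng.uniform(size=codec.n_bits) <= prob).astype(np.uint8)
            bits = codec.ensure_valid(
                bits, rng,
                redraw=lambda sl: (rng.uniform(size=sl.stop - sl.start)
                                   <= prob[sl]).astype(np.uint8))
            x[k] = bits
            sol = _evaluate(codec.decode(bits), objective, trace)
            if sol.f < pbest[k].f:
                pbest[k] = sol
            if sol.f < gbest.f:
                gbest = sol
        trace.close_generation()
    return trace


# ---------------------------------------------------------------------------
# Artificial fish swarm
# ---------------------------------------------------------------------------

def _hamming(a, b) -> int:
    return int(np.sum(a != b))


def _move_toward(codec, bits_from, target, rng):
    """Keep bits equal to the target; redraw differing bits with a fair coin
    (1 iff rand <= 0.5), then restore validity."""
    out = bits_from.copy()
    diff = np.flatnonzero(bits_from != target)
    out[diff] = (rng.uniform(size=len(diff)) <= 0.5).astype(np.uint8)
    return codec.ensure_valid(out, rng)


def _random_visual_state(codec, bits, visual, rng):
    """A random valid state within Hamming distance ``visual``."""
    k = int(rng.randint(1, visual + 1))
    pos = rng.choice(len(bits), size=min(k, len(bits)), replace=False)
    out = bits.copy()
    out[pos] ^= 1
    return codec.ensure_valid(out, rng)


def afsa_optimize(objective, codec: BitCodec, params: OptimizerParams = None,
                  seed=0) -> OptimizerTrace:
    """Artificial fish swarm over bit strings with Hamming-ball vision.

    For each fish, the swarm move (toward the neighbourhood's majority-bit
    centre) and the follow move (toward the best neighbour) are both tried
    when their crowding conditions ``F_centre/nf > delta*F_i`` resp.
    ``F_best/nf > delta*F_i`` hold, and the fitter outcome is kept;
    otherwise the fish preys: up to ``try_number`` random states within the
    visual range, moving toward the first improvement, else a random step.
    """
    params = params or OptimizerParams()
    if params.popsize < 2:
        raise ValueError("popsize must be >= 2")
    rng = np.random.RandomState(seed)
    trace = OptimizerTrace()
    pop = _init_population(codec, rng, objective, trace, params.popsize)
    for _ in range(params.maxgen):
        for k in range(params.popsize):
            fish = pop[k]
            nbrs = [s for j, s in enumerate(pop)
                    if j != k and _hamming(s.bits, fish.bits) <= params.visual]
            candidates = []
            if nbrs:
                nf = len(nbrs)
                stack = np.array([s.bits for s in nbrs], dtype=float)
                centre_bits = (stack.mean(axis=0) > 0.5).astype(np.uint8)
                tie = stack.mean(axis=0) == 0.5
                centre_bits[tie] = fish.bits[tie]
                centre = _evaluate(
                    codec.decode(codec.ensure_valid(centre_bits, rng)),
                    objective, trace)
                if centre.fitness / nf > params.delta * fish.fitness:
                    moved = _move_toward(codec, fish.bits, centre.bits, rng)
                    candidates.append(_evaluate(codec.decode(moved),
                                                objective, trace))
                best_nb = min(nbrs, key=lambda s: s.f)
                if best_nb.fitness / nf > params.delta * fish.fitness:
                    moved = _move_toward(codec, fish.bits, best_nb.bits, rng)
                    candidates.append(_evaluate(codec.decode(moved),
                                                objective, trace))
            if candidates:
                pop[k] = min(candidates, key=lambda s: s.f)
                continue
            # prey
            moved_any = False
            for _t in range(params.try_number):
                probe = _evaluate(
                    codec.decode(_random_visual_state(codec, fish.bits,
                                                      params.visual, rng)),
                    objective, trace)
                if probe.f < fish.f:
                    moved = _move_toward(codec, fish.bits, probe.bits, rng)
                    pop[k] = _evaluate(codec.decode(moved), objective, trace)
                    moved_any = True
                    break
            if not moved_any:
                step = _random_visual_state(codec, fish.bits, params.visual, rng)
                pop[k] = _evaluate(codec.decode(step), objective, trace)
        trace.close_generation()
    return trace


ENGINES = {"ga": ga_optimize, "pso": pso_optimize, "afsa": afsa_optimize}


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class BaseHybridForest(BaseEstimator, ClassifierMixin):
    """Metaheuristic-tuned random forest.

    ``fit`` searches (nTree, kappa, feature mask) minimising the forest's
    OOB error on the training data, then refits a final forest on the
    selected features.  Fitted attributes: ``best_ntree_``, ``best_kappa_``,
    ``selected_features_``, ``best_oob_error_``, ``trace_``, ``forest_``.
    """

    engine = None

    def __init__(self, popsize=5, maxgen=20, pc=0.6, pm=0.1, c1=1.5, c2=1.5,
                 w=0.5, v_init=0.5, v_clamp=None, visual=3, try_number=5,
                 delta=0.618, max_depth=20, min_leaf=1, random_state=None,
                 objective_cache=None):
        self.popsize = popsize
        self.maxgen = maxgen
        self.pc = pc
        self.pm = pm
        self.c1 = c1
        self.c2 = c2
        self.w = w
        self.v_init = v_init
        self.v_clamp = v_clamp
        self.visual = visual
        self.try_number = try_number
        self.delta = delta
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.random_state = random_state
        # optional shared memo dict: runs with identical data and seed may
        # reuse each other's (bits -> OOB error) evaluations
        self.objective_cache = objective_cache

    def _opt_params(self) -> OptimizerParams:
        return OptimizerParams(
            popsize=self.popsize, maxgen=self.maxgen, pc=self.pc, pm=self.pm,
            c1=self.c1, c2=self.c2, w=self.w, v_init=self.v_init,
            v_clamp=self.v_clamp, visual=self.visual,
            try_number=self.try_number, delta=self.delta)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        seed = int(self.random_state or 0) % (2 ** 31 - 1)
        codec = BitCodec(X.shape[1])
        objective = make_forest_objective(
            X, y, max_depth=self.max_depth, min_leaf=self.min_leaf,
            forest_seed=seed, cache=self.objective_cache)
        trace = ENGINES[self.engine](objective, codec, self._opt_params(),
                                     seed=seed)
        best = trace.best
        self.codec_ = codec
        self.trace_ = trace
        self.best_solution_ = best
        self.best_ntree_ = best.n_tree
        self.best_kappa_ = best.kappa
        self.selected_features_ = np.flatnonzero(best.mask)
        self.best_oob_error_ = best.f
        self.forest_ = RandomForest(
            n_trees=best.n_tree, kappa=best.kappa, max_depth=self.max_depth,
            min_leaf=self.min_leaf, random_state=seed,
        ).fit(np.ascontiguousarray(X[:, self.selected_features_]), y)
        self.classes_ = self.forest_.classes_
        return self

    def _mask_X(self, X):
        return np.ascontiguousarray(
            np.asarray(X, dtype=float)[:, self.selected_features_])

    def predict(self, X):
        return self.forest_.predict(self._mask_X(X))

    def predict_proba(self, X):
        return self.forest_.predict_proba(self._mask_X(X))


class GARandomForest(BaseHybridForest):
    """Genetic-algorithm-tuned random forest."""

    engine = "ga"


class PSORandomForest(BaseHybridForest):
    """Binary-PSO-tuned random forest."""

    engine = "pso"


class AFSARandomForest(BaseHybridForest):
    """Artificial-fish-swarm-tuned random forest."""

    engine = "afsa"


OPTIMIZERS = {"ga": GARandomForest, "pso": PSORandomForest,
              "afsa": AFSARandomForest}
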