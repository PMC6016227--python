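"""Black-hole metaheuristic over candidate classifier configurations.

The black hole algorithm is a population-based search: each *star* is a
candidate solution; the best star is the *black hole*.  Per iteration
every star is evaluated, a better star swaps places with the black
hole, all other stars move toward the black hole by the absorption rule

    x_i(t+1) = x_i(t) + alpha * (x_bh - x_i(t)),   alpha ~ U(0, 1),

and stars that fall inside the event horizon of radius

    R = f_bh / sum_i f_i

are destroyed and re-seeded uniformly at random, which prevents the
population from collapsing onto a local optimum.  The historically best
star is returned (elitism: the reported best-so-far trace never
decreases).

Here a star encodes a perturbation of the classifier configuration:
additive offsets on the 8 training-feature columns and/or log10 of the
SVM's C and gamma.  Fitness is the accuracy of the resulting classifier
on an untouched evaluation split — evaluation rows are never perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .classifier import SvmConfig, accuracy, default_gamma, train

__all__ = [
    "Star",
    "SearchSpace",
    "EvalContext",
    "BlackHoleOptions",
    "init_population",
    "move_star",
    "event_horizon",
    "absorb_or_keep",
    "evaluate",
    "optimize",
]

Mode = Literal["feature_perturbation", "hyperparameters", "both"]


def _standardized_gamma(X: np.ndarray) -> float:
    """Default kernel width of the matrix after per-column standardization,
    matching what the classifier uses when no gamma is supplied."""
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - X.mean(axis=0)) / sd
    return default_gamma(Xs)


@dataclass
class Star:
    """A candidate solution: position in the search space + fitness."""

    position: np.ndarray
    fitness: float | None = None


@dataclass(frozen=True)
class BlackHoleOptions:
    """Behavioural switches of the optimizer.

    ``horizon_rule`` selects absorption by normalized distance (the
    standard, stable rule: absorb when distance < R) or by probability
    (absorb when u ~ U(0,1) < R).  ``horizon_excludes_bh`` drops the
    black hole's own fitness from the denominator of R.
    ``alpha_per_component`` draws one alpha per coordinate instead of a
    single scalar per star.
    """

    horizon_rule: Literal["distance", "probability"] = "distance"
    horizon_excludes_bh: bool = False
    alpha_per_component: bool = False
    use_event_horizon: bool = True


@dataclass
class SearchSpace:
    """Encoding between star positions and classifier configurations.

    ``mode`` picks which block of the position is active:

    * ``feature_perturbation`` — 8 additive offsets on the training
      feature columns;
    * ``hyperparameters`` — [log10 C, log10 gamma];
    * ``both`` — the 10-dimensional concatenation (default).

    ``lower``/``upper`` are per-component bounds; decoding any
    in-bounds position yields a valid trainable configuration.
    """

    mode: Mode
    lower: np.ndarray
    upper: np.ndarray
    n_features: int = 8

    @property
    def dimension(self) -> int:
        return self.lower.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower, self.upper)

    def decode(
        self, position: np.ndarray, X_train: np.ndarray, base_config: SvmConfig
    ) -> tuple[np.ndarray, SvmConfig]:
        """In-bounds position -> (perturbed training matrix, SvmConfig)."""
        pos = np.asarray(position, dtype=float)
        if pos.size != self.dimension:
            raise ValueError(f"position has {pos.size} components, expected {self.dimension}")
        if np.any(pos < self.lower - 1e-12) or np.any(pos > self.upper + 1e-12):
            raise ValueError("position out of bounds")
        X = X_train
        config = base_config
        if self.mode in ("feature_perturbation", "both"):
            offsets = pos[: self.n_features]
            X = X_train + offsets[np.newaxis, :]
        if self.mode in ("hyperparameters", "both"):
            log_c, log_gamma = pos[-2:]
            config = SvmConfig(
                C=10.0**log_c, gamma=10.0**log_gamma, class_weights=base_config.class_weights
            )
        return X, config

    @classmethod
    def for_features(
        cls,
        X_train: np.ndarray,
        mode: Mode = "both",
        offset_scale: float = 1.0,
        log_c_bounds: tuple[float, float] = (-2.0, 2.0),
        log_gamma_halfwidth: float = 2.0,
    ) -> "SearchSpace":
        """Bounds derived from the training matrix.

        Feature offsets range over ±``offset_scale`` column SDs; log10 C
        over ``log_c_bounds``; log10 gamma over ±``log_gamma_halfwidth``
        around the default kernel width of the (standardized) matrix.
        """
        n_features = X_train.shape[1]
        sds = X_train.std(axis=0)
        sds[sds == 0] = 1.0
        blocks_lo: list[np.ndarray] = []
        blocks_hi: list[np.ndarray] = []
        if mode in ("feature_perturbation", "both"):
            blocks_lo.append(-offset_scale * sds)
            blocks_hi.append(offset_scale * sds)
        if mode in ("hyperparameters", "both"):
            log_gamma0 = np.log10(_standardized_gamma(X_train))
            blocks_lo.append(np.array([log_c_bounds[0], log_gamma0 - log_gamma_halfwidth]))
            blocks_hi.append(np.array([log_c_bounds[1], log_gamma0 + log_gamma_halfwidth]))
        return cls(
            mode=mode,
            lower=np.concatenate(blocks_lo),
            upper=np.concatenate(blocks_hi),
            n_features=n_features,
        )

    def base_position(self, base_config: SvmConfig, X_train: np.ndarray) -> np.ndarray:
        """The identity point: zero offsets, the base C and gamma."""
        parts: list[np.ndarray] = []
        if self.mode in ("feature_perturbation", "both"):
            parts.append(np.zeros(self.n_features))
        if self.mode in ("hyperparameters", "both"):
            gamma = (
                base_config.gamma
                if base_config.gamma is not None
                else _standardized_gamma(X_train)
            )
            parts.append(np.array([np.log10(base_config.C), np.log10(gamma)]))
        return self.clip(np.concatenate(parts))


@dataclass
class EvalContext:
    """Frozen train/eval split and base config used for every fitness call."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_eval: np.ndarray
    y_eval: np.ndarray
    base_config: SvmConfig = field(default_factory=SvmConfig)


def evaluate(star: Star, space: SearchSpace, ctx: EvalContext) -> float:
    """Fitness: accuracy of the decoded classifier on the untouched eval split."""
    X_train, config = space.decode(star.position, ctx.X_train, ctx.base_config)
    model = train(X_train, ctx.y_train, config)
    fit = accuracy(model, ctx.X_eval, ctx.y_eval)
    star.fitness = fit
    return fit


def init_population(
    base: np.ndarray,
    n: int,
    error0: float,
    rng: np.random.Generator,
    space: SearchSpace,
) -> list[Star]:
    """Population seeded around the baseline solution.

    Star 0 is the unperturbed base; stars 1..n-1 are Gaussian
    perturbations whose per-component SD is ``error0`` (the baseline
    classifier's error rate) times the component's bound half-width, so
    a worse baseline explores more aggressively.  All positions are
    clipped to bounds.
    """
    if n < 2:
        raise ValueError("population needs at least 2 stars")
    if not 0.0 <= error0 <= 1.0:
        raise ValueError("error0 must be in [0, 1]")
    base = space.clip(np.asarray(base, dtype=float))
    scale = error0 * 0.5 * space.width
    stars = [Star(position=base.copy())]
    for _ in range(n - 1):
        pos = base + rng.normal(0.0, 1.0, size=space.dimension) * scale
        stars.append(Star(position=space.clip(pos)))
    return stars


def move_star(
    x_i: np.ndarray,
    x_bh: np.ndarray,
    rng: np.random.Generator,
    space: SearchSpace | None = None,
    per_component: bool = False,
) -> np.ndarray:
    """Absorption move: x + alpha * (x_bh - x), alpha ~ U(0,1).

    One scalar alpha per star by default (per-component available).
    Result clipped to bounds when a space is given.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_bh = np.asarray(x_bh, dtype=float)
    if x_i.shape != x_bh.shape:
        raise ValueError("dimension mismatch between star and black hole")
    alpha = rng.uniform(0.0, 1.0, size=x_i.size if per_component else None)
    out = x_i + alpha * (x_bh - x_i)
    return space.clip(out) if space is not None else out


def event_horizon(f_bh: float, fitnesses: list[float], exclude_bh: bool = False) -> float:
    """Event-horizon radius R = f_bh / sum(f_i) over all stars.

    ``exclude_bh`` drops one occurrence of f_bh from the denominator.
    """
    total = float(np.sum(fitnesses))
    if exclude_bh:
        total -= f_bh
    if total <= 0:
        raise ValueError("total fitness must be positive")
    return f_bh / total


def _normalized_distance(a: np.ndarray, b: np.ndarray, space: SearchSpace) -> float:
    w = space.width.copy()
    w[w == 0] = 1.0
    return float(np.linalg.norm((a - b) / w))


def absorb_or_keep(
    star: Star,
    bh: Star,
    R: float,
    rng: np.random.Generator,
    space: SearchSpace,
    rule: Literal["distance", "probability"] = "distance",
) -> Star:
    """Destroy-and-respawn rule for stars inside the event horizon.

    Distance rule (default): replace when the normalized Euclidean
    distance to the black hole (components scaled by bound widths) is
    below R.  Probability rule: replace when u ~ U(0,1) < R.  A
    replacement is a fresh uniform in-bounds star with unevaluated
    fitness.
    """
    if rule == "distance":
        absorbed = _normalized_distance(star.position, bh.position, space) < R
    else:
        absorbed = rng.uniform() < R
    if not absorbed:
        return star
    fresh = space.lower + rng.uniform(size=space.dimension) * space.width
    return Star(position=fresh, fitness=None)


@dataclass
class OptimizeResult:
    """Best star ever seen, its fitness, and bookkeeping traces."""

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness per iteration, length T
    n_absorbed: int = 0


def optimize(
    space: SearchSpace,
    ctx: EvalContext,
    n: int = 30,
    T: int = 100,
    seed: int = 0,
    options: BlackHoleOptions | None = None,
    fitness_fn: Callable[[Star], float] | None = None,
    base: np.ndarray | None = None,
    error0: float | None = None,
) -> OptimizeResult:
    """Run the black-hole search.

    Per iteration: evaluate all stars; swap the black hole with any
    better star; move every non-black-hole star by the absorption rule;
    apply the event horizon.  Returns the historically best star and
    the best-so-far trace (length ``T``, monotone nondecreasing).

    ``fitness_fn`` overrides classifier evaluation (used for toy
    objectives); ``base``/``error0`` seed the initial population — by
    default the base is the identity configuration and ``error0`` is
    its error rate.
    """
    options = options or BlackHoleOptions()
    rng = np.random.default_rng(seed)
    fit = fitness_fn if fitness_fn is not None else (lambda s: evaluate(s, space, ctx))

    if base is None:
        base = space.base_position(ctx.base_config, ctx.X_train)
    base_star = Star(position=space.clip(np.asarray(base, dtype=float)))
    base_fitness = fit(base_star)
    if error0 is None:
        error0 = 1.0 - base_fitness
    stars = init_population(base_star.position, n, error0, rng, space)
    stars[0].fitness = base_fitness

    # Evaluate the initial population so best-ever is defined even at T=0.
    for star in stars:
        if star.fitness is None:
            fit(star)
    init_best = int(np.argmax([s.fitness for s in stars]))
    best_position = stars[init_best].position.copy()
    best_fitness = stars[init_best].fitness
    trace = np.empty(T)
    n_absorbed = 0

    for t in range(T):
        for star in stars:
            if star.fitness is None:
                fit(star)
        fitnesses = [s.fitness for s in stars]
        bh_index = int(np.argmax(fitnesses))
        bh = stars[bh_index]
        if bh.fitness > best_fitness:
            best_fitness = bh.fitness
            best_position = bh.position.copy()
        trace[t] = best_fitness

        for i, star in enumerate(stars):
            if i == bh_index:
                continue
            star.position = move_star(
                star.position, bh.position, rng, space, per_component=options.alpha_per_component
            )
            star.fitness = None  # moved: must be re-evaluated

        if options.use_event_horizon:
            R = event_horizon(bh.fitness, fitnesses, exclude_bh=options.horizon_excludes_bh)
            for i, star in enumerate(stars):
                if i == bh_index:
                    continue
                replacement = absorb_or_keep(star, bh, R, rng, space, rule=options.horizon_rule)
                if replacement is not star:
                    n_absorbed += 1
                    stars[i] = replacement

    return OptimizeResult(
        best_position=best_position,
        best_fitness=best_fitness,
        trace=trace,
        n_absorbed=n_absorbed,
    )
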