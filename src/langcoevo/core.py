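"""Core agent/language state machine.

One generation runs, in order: all-pairs communication, fitness evaluation,
roulette-wheel reproduction with Gaussian mutation, then the four cultural
processes on the language population (change + division from a single
displacement pass, extinction, fusion).  Every stochastic draw consumes a
single seeded :class:`numpy.random.Generator`, in a fixed documented order,
so identical seed + parameters give bit-identical traces.

Positions live on a one-dimensional axis: an agent has an innate ability
``a`` (the language it can use at zero learning cost) and a plasticity
half-width ``p`` (it can learn any language inside ``[a - p, a + p]`` at an
exponential fitness cost).  A language is a point whose coordinate is its
expressiveness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "Agent",
    "Language",
    "LanguagePopulation",
    "AgentPopulation",
    "CommunicationLog",
    "CulturalEvent",
    "RunTrace",
    "SimState",
    "shared_languages",
    "run_communication_round",
    "compute_fitness",
    "compute_fitness_all",
    "selection_weights",
    "reproduce",
    "displacement",
    "displacements_all",
    "apply_cultural_change",
    "apply_extinction",
    "apply_fusion",
    "step_generation",
    "run_simulation",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimParams:
    """Run configuration.

    Defaults are the headline configuration: ``N=2000``, ``W1=3``, ``W2=10``,
    ``Pm=0.001``, ``F=0.001``, ``Fd=0.008``, ``Tf=0.02``, 10,000 generations,
    with genotypes and language positions initialised uniformly on [0, 1].

    Parameters
    ----------
    N : int
        Number of agents; constant over a run.
    W1, W2 : float
        Weights of the communication benefit and the plasticity cost in the
        fitness function.
    Pm : float
        Per-genotype mutation probability (applied independently to ``a``
        and ``p`` of each offspring).
    mut_var : float
        Variance of the zero-mean Gaussian mutation kick.
    F : float
        Cultural displacement unit: each user of a language pulls it by
        ``F / n_i`` toward its own innate ability, where ``n_i`` is the
        user's repertoire size.
    Fd : float
        Division threshold on ``min(d_plus, |d_minus|)``.
    Tf : float
        Fusion threshold: two languages closer than this merge at their
        midpoint.
    generations : int
        Run length.
    init_num_languages : int
        Initial language count (free parameter; the source model does not
        pin it down, see the package docs).
    seed : int
        RNG seed for the whole run.
    fitness_floor : float
        Small positive floor applied to fitness when forming roulette
        weights, so that non-positive fitness still yields a valid (tiny)
        selection weight.
    displacement_weighting : str
        ``"per_user"`` (default): each distinct user of a language
        contributes ``F / n_i`` once, as in the displacement equations.
        ``"per_event"``: every successful communication contributes, so an
        agent using a language in k pairs pulls k times — an alternative
        reading under which high displacement units reproduce the reported
        early total-extinction regime (see the package docs).
    """

    N: int = 2000
    W1: float = 3.0
    W2: float = 10.0
    Pm: float = 0.001
    mut_var: float = 2.0
    F: float = 0.001
    Fd: float = 0.008
    Tf: float = 0.02
    generations: int = 10_000
    init_num_languages: int = 100
    seed: int = 0
    fitness_floor: float = 1e-6
    displacement_weighting: str = "per_user"

    def __post_init__(self) -> None:
        if self.displacement_weighting not in ("per_user", "per_event"):
            raise ValueError(
                "displacement_weighting must be 'per_user' or 'per_event'")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.W1 < 0 or self.W2 < 0:
            raise ValueError("W1 and W2 must be >= 0")
        if not 0.0 <= self.Pm <= 1.0:
            raise ValueError("Pm must be in [0, 1]")
        if self.mut_var < 0:
            raise ValueError("mut_var must be >= 0")
        if self.F < 0:
            raise ValueError("F must be >= 0")
        if self.Fd <= 0 or self.Tf <= 0:
            raise ValueError("Fd and Tf must be > 0")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.init_num_languages < 1:
            raise ValueError("init_num_languages must be >= 1")
        if self.fitness_floor <= 0:
            raise ValueError("fitness_floor must be > 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_mapping(cls, mapping: Mapping, **overrides) -> "SimParams":
        known = {f.name for f in fields(cls)}
        data = {k: v for k, v in dict(mapping).items() if k in known}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Agent:
    """A single agent: innate ability ``a`` >= 0, plasticity ``p`` >= 0."""

    a: float
    p: float
    fitness: float = 0.0

    @property
    def interval(self) -> tuple[float, float]:
        """Plasticity interval ``[a - p, a + p]``."""
        return (self.a - self.p, self.a + self.p)


@dataclass(frozen=True)
class Language:
    """A language: position (expressiveness) and a stable lineage id.

    The lineage id survives cultural change; division and fusion retire the
    parent id(s) and mint fresh ones.
    """

    pos: float
    lineage_id: int


@dataclass
class AgentPopulation:
    """Column-oriented agent population (``a``, ``p``, ``fitness`` arrays)."""

    a: np.ndarray
    p: np.ndarray
    fitness: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.fitness = np.asarray(self.fitness, dtype=float)
        if not (len(self.a) == len(self.p) == len(self.fitness)):
            raise ValueError("a, p, fitness must have equal length")

    def __len__(self) -> int:
        return len(self.a)

    @classmethod
    def from_agents(cls, agents: Sequence[Agent]) -> "AgentPopulation":
        return cls(
            a=np.array([ag.a for ag in agents], dtype=float),
            p=np.array([ag.p for ag in agents], dtype=float),
            fitness=np.array([ag.fitness for ag in agents], dtype=float),
        )

    @classmethod
    def random(cls, n: int, rng: np.random.Generator) -> "AgentPopulation":
        """Draw ``a`` then ``p`` i.i.d. uniform on [0, 1] (fixed RNG order)."""
        a = rng.uniform(0.0, 1.0, size=n)
        p = rng.uniform(0.0, 1.0, size=n)
        return cls(a=a, p=p, fitness=np.zeros(n))

    def agents(self) -> list[Agent]:
        return [Agent(float(a), float(p), float(f))
                for a, p, f in zip(self.a, self.p, self.fitness)]


class LanguagePopulation:
    """Set of languages kept sorted by position.

    Carries ``next_id``, the next unused lineage id, so division and fusion
    can mint fresh identifiers without global state.
    """

    __slots__ = ("positions", "lineage_ids", "next_id")

    def __init__(self, positions, lineage_ids, next_id: int | None = None):
        pos = np.asarray(positions, dtype=float)
        lid = np.asarray(lineage_ids, dtype=np.int64)
        if pos.shape != lid.shape:
            raise ValueError("positions and lineage_ids must match in shape")
        if len(np.unique(lid)) != len(lid):
            raise ValueError("lineage ids must be unique")
        order = np.lexsort((lid, pos))
        self.positions = pos[order]
        self.lineage_ids = lid[order]
        if next_id is None:
            next_id = int(lid.max()) + 1 if len(lid) else 0
        self.next_id = int(next_id)

    @classmethod
    def from_positions(cls, positions, start_id: int = 0) -> "LanguagePopulation":
        pos = np.asarray(positions, dtype=float)
        ids = np.arange(start_id, start_id + len(pos), dtype=np.int64)
        return cls(pos, ids)

    @classmethod
    def random(cls, n: int, rng: np.random.Generator) -> "LanguagePopulation":
        return cls.from_positions(rng.uniform(0.0, 1.0, size=n))

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self) -> Iterator[Language]:
        for pos, lid in zip(self.positions, self.lineage_ids):
            yield Language(float(pos), int(lid))

    def as_set(self) -> set[Language]:
        return set(self)

    def mean_position(self) -> float:
        return float(np.mean(self.positions)) if len(self) else math.nan


@dataclass
class CulturalEvent:
    """One cultural process occurrence (change/division/fusion/extinction)."""

    kind: str
    generation: int
    parent_positions: tuple[float, ...]
    child_positions: tuple[float, ...]
    parent_lineages: tuple[int, ...]
    child_lineages: tuple[int, ...]

    _ARITY = {  # kind -> (n_parents, n_children)
        "change": (1, 1),
        "division": (1, 2),
        "fusion": (2, 1),
        "extinction": (1, 0),
    }

    def __post_init__(self) -> None:
        if self.kind not in self._ARITY:
            raise ValueError(f"unknown event kind {self.kind!r}")
        np_, nc = self._ARITY[self.kind]
        if len(self.parent_positions) != np_ or len(self.child_positions) != nc:
            raise ValueError(
                f"{self.kind} event requires {np_} parent(s) and {nc} child(ren)"
            )
        if len(self.parent_lineages) != np_ or len(self.child_lineages) != nc:
            raise ValueError("lineage tuples must match position tuples")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "generation": self.generation,
            "parent_positions": list(self.parent_positions),
            "child_positions": list(self.child_positions),
            "parent_lineages": list(self.parent_lineages),
            "child_lineages": list(self.child_lineages),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CulturalEvent":
        return cls(
            kind=d["kind"],
            generation=int(d["generation"]),
            parent_positions=tuple(float(x) for x in d["parent_positions"]),
            child_positions=tuple(float(x) for x in d["child_positions"]),
            parent_lineages=tuple(int(x) for x in d["parent_lineages"]),
            child_lineages=tuple(int(x) for x in d["child_lineages"]),
        )


@dataclass
class CommunicationLog:
    """Outcome of one all-pairs communication round.

    Stored column-wise for speed; the mapping-style views used in the
    contracts (``successes``, ``users``) are built on demand and meant for
    inspection and small tests.

    ``pair_i``/``pair_j``/``pair_lang`` list each successful unordered pair
    once, with the index (into ``lang_positions``) of the single shared
    language drawn uniformly for that pair and used by *both* partners.
    ``usable_counts[i]`` is the number of languages inside agent *i*'s
    plasticity interval at communication time (the repertoire size ``n_i``).
    ``agent_a`` and the language snapshot arrays freeze the state the log
    was computed from.
    """

    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_lang: np.ndarray
    lang_positions: np.ndarray
    lang_lineages: np.ndarray
    agent_a: np.ndarray
    usable_counts: np.ndarray
    _incidence: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_agents(self) -> int:
        return len(self.agent_a)

    @property
    def n_successes(self) -> int:
        return len(self.pair_i)

    def user_incidence(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique (agent index, language index) usage pairs."""
        if self._incidence is None:
            nL = max(len(self.lang_positions), 1)
            agents = np.concatenate([self.pair_i, self.pair_j])
            langs = np.concatenate([self.pair_lang, self.pair_lang])
            codes = np.unique(agents.astype(np.int64) * nL + langs)
            self._incidence = (codes // nL, codes % nL)
        return self._incidence

    def successes(self) -> dict[int, set[tuple[int, float]]]:
        """Mapping agent index -> set of (partner index, used-language position)."""
        out: dict[int, set[tuple[int, float]]] = {}
        for i, j, k in zip(self.pair_i, self.pair_j, self.pair_lang):
            pos = float(self.lang_positions[k])
            out.setdefault(int(i), set()).add((int(j), pos))
            out.setdefault(int(j), set()).add((int(i), pos))
        return out

    def users(self) -> dict[int, set[int]]:
        """Mapping language lineage id -> set of agent indices that used it."""
        ua, ul = self.user_incidence()
        out: dict[int, set[int]] = {}
        for a, k in zip(ua, ul):
            out.setdefault(int(self.lang_lineages[k]), set()).add(int(a))
        return out

    def user_counts(self) -> np.ndarray:
        """Per-language (snapshot order) count of distinct users."""
        counts = np.zeros(len(self.lang_positions), dtype=np.int64)
        ua, ul = self.user_incidence()
        np.add.at(counts, ul, 1)
        return counts


@dataclass
class RunTrace:
    """Per-generation summary series plus the full cultural event log.

    ``mean_a``/``mean_p`` describe the end-of-generation (offspring)
    population; ``mean_fitness`` describes the communicating (parent)
    population; ``mean_lang_pos``/``n_langs`` describe the language
    population after all cultural processes; ``n_successes`` counts the
    successful pairs of the round.  ``mean_lang_pos`` is NaN whenever the
    language population is empty.
    """

    params: SimParams
    gen: np.ndarray
    mean_a: np.ndarray
    mean_p: np.ndarray
    mean_fitness: np.ndarray
    mean_lang_pos: np.ndarray
    n_langs: np.ndarray
    n_successes: np.ndarray
    events: list[CulturalEvent] = field(default_factory=list)
    total_extinction_generation: int | None = None
    snapshots: dict[int, dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gen)

    COLUMNS = ("gen", "mean_a", "mean_p", "mean_fitness",
               "mean_lang_pos", "n_langs", "n_successes")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in self.COLUMNS})

    # -- persistence (plain-text formats only) ------------------------------

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out / "trace.csv", index=False)
        with open(out / "events.jsonl", "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev.to_dict()) + "\n")
        meta = {
            "params": self.params.to_dict(),
            "total_extinction_generation": self.total_extinction_generation,
        }
        with open(out / "params.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def read(cls, run_dir) -> "RunTrace":
        from pathlib import Path

        run = Path(run_dir)
        df = pd.read_csv(run / "trace.csv")
        with open(run / "params.json") as fh:
            meta = json.load(fh)
        events: list[CulturalEvent] = []
        ev_path = run / "events.jsonl"
        if ev_path.exists():
            with open(ev_path) as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        events.append(CulturalEvent.from_dict(json.loads(line)))
        return cls(
            params=SimParams.from_mapping(meta["params"]),
            gen=df["gen"].to_numpy(),
            mean_a=df["mean_a"].to_numpy(),
            mean_p=df["mean_p"].to_numpy(),
            mean_fitness=df["mean_fitness"].to_numpy(),
            mean_lang_pos=df["mean_lang_pos"].to_numpy(),
            n_langs=df["n_langs"].to_numpy(),
            n_successes=df["n_successes"].to_numpy(),
            events=events,
            total_extinction_generation=meta.get("total_extinction_generation"),
        )


@dataclass
class SimState:
    """Full simulator state between generations."""

    agents: AgentPopulation
    langs: LanguagePopulation
    generation: int = 0


# ---------------------------------------------------------------------------
# communication
# ---------------------------------------------------------------------------


def shared_languages(agent_i: Agent, agent_j: Agent,
                     langs: LanguagePopulation) -> set[Language]:
    """Languages inside the intersection of both agents' plasticity intervals.

    Returns the empty set when the interval intersection is empty or holds
    no language.  Boundaries are inclusive on both sides.
    """
    lo = max(agent_i.a - agent_i.p, agent_j.a - agent_j.p)
    hi = min(agent_i.a + agent_i.p, agent_j.a + agent_j.p)
    if lo > hi or len(langs) == 0:
        return set()
    left = int(np.searchsorted(langs.positions, lo, side="left"))
    right = int(np.searchsorted(langs.positions, hi, side="right"))
    return {
        Language(float(langs.positions[k]), int(langs.lineage_ids[k]))
        for k in range(left, right)
    }


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def run_communication_round(
    agents: AgentPopulation | Sequence[Agent],
    langs: LanguagePopulation,
    rng: np.random.Generator,
    pair_idx: tuple[np.ndarray, np.ndarray] | None = None,
) -> CommunicationLog:
    """One all-pairs round: every unordered pair with a non-empty shared
    language set succeeds, and one shared language is drawn uniformly for the
    pair (the same draw is recorded for both partners).

    Shared sets are resolved with interval queries against the sorted
    language positions (``O(P log L)`` over ``P`` pairs), which agrees
    exactly with per-pair brute force; ``pair_idx`` lets callers reuse the
    upper-triangle index arrays across generations.
    """
    if not isinstance(agents, AgentPopulation):
        agents = AgentPopulation.from_agents(list(agents))
    n = len(agents)
    if n < 2:
        raise ValueError("communication needs at least 2 agents")
    L = langs.positions
    lo = agents.a - agents.p
    hi = agents.a + agents.p
    usable = (
        np.searchsorted(L, hi, side="right") - np.searchsorted(L, lo, side="left")
    ).astype(np.int64)
    np.maximum(usable, 0, out=usable)

    if pair_idx is None:
        pair_idx = _pair_indices(n)
    iu, ju = pair_idx
    pair_lo = np.maximum(lo[iu], lo[ju])
    pair_hi = np.minimum(hi[iu], hi[ju])
    left = np.searchsorted(L, pair_lo, side="left")
    right = np.searchsorted(L, pair_hi, side="right")
    counts = right - left
    ok = counts > 0
    left_ok = left[ok]
    right_ok = right[ok]
    if len(left_ok):
        chosen = rng.integers(left_ok, right_ok)
    else:
        chosen = np.zeros(0, dtype=np.int64)
    return CommunicationLog(
        pair_i=iu[ok].astype(np.int64),
        pair_j=ju[ok].astype(np.int64),
        pair_lang=chosen.astype(np.int64),
        lang_positions=L.copy(),
        lang_lineages=langs.lineage_ids.copy(),
        agent_a=agents.a.copy(),
        usable_counts=usable,
    )


# ---------------------------------------------------------------------------
# fitness and reproduction
# ---------------------------------------------------------------------------


def compute_fitness_all(agents: AgentPopulation, log: CommunicationLog,
                        params: SimParams) -> np.ndarray:
    """Vectorised fitness: ``W1 * sum of used-language positions - W2 * (p+1)**a``.

    Each successful pair contributes its chosen language's position to both
    partners' benefit sums.
    """
    n = len(agents)
    benefit = np.zeros(n)
    if log.n_successes:
        used = log.lang_positions[log.pair_lang]
        benefit += np.bincount(log.pair_i, weights=used, minlength=n)
        benefit += np.bincount(log.pair_j, weights=used, minlength=n)
    return params.W1 * benefit - params.W2 * (agents.p + 1.0) ** agents.a


def compute_fitness(agent: Agent, log: CommunicationLog, params: SimParams,
                    index: int = 0) -> float:
    """Fitness of the agent at ``index`` in the log's population."""
    mask_i = log.pair_i == index
    mask_j = log.pair_j == index
    used = log.lang_positions[log.pair_lang]
    benefit = float(used[mask_i].sum() + used[mask_j].sum())
    return params.W1 * benefit - params.W2 * (agent.p + 1.0) ** agent.a


def selection_weights(fitnesses: np.ndarray, fitness_floor: float) -> np.ndarray:
    """Roulette weights: ``max(fitness, fitness_floor)``.

    Selection probability stays proportional to fitness wherever fitness is
    positive; non-positive fitness collapses to the (tiny, equal) floor so
    the wheel is always well defined.
    """
    if fitness_floor <= 0:
        raise ValueError("fitness_floor must be > 0")
    f = np.asarray(fitnesses, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("fitness values must be finite")
    return np.maximum(f, fitness_floor)


def reproduce(agents: AgentPopulation, fitnesses: np.ndarray,
              params: SimParams, rng: np.random.Generator) -> AgentPopulation:
    """Produce exactly N offspring by fitness-proportional roulette selection.

    Each offspring copies its parent's genotypes; ``a`` and ``p`` are then
    independently perturbed, each with probability ``Pm``, by a Gaussian
    kick with mean 0 and variance ``mut_var``, and clamped at 0.

    RNG order: parent draws, then the two mutation masks, then the two
    mutation kicks (the kick arrays are drawn even where the mask is off, so
    the stream layout does not depend on outcomes).
    """
    n = len(agents)
    w = selection_weights(fitnesses, params.fitness_floor)
    total = w.sum()
    if not total > 0:
        raise ValueError("all selection weights are zero")
    parents = rng.choice(n, size=n, p=w / total)
    a_new = agents.a[parents].copy()
    p_new = agents.p[parents].copy()
    mask = rng.random((2, n)) < params.Pm
    kick = rng.normal(0.0, math.sqrt(params.mut_var), size=(2, n))
    a_new[mask[0]] += kick[0][mask[0]]
    p_new[mask[1]] += kick[1][mask[1]]
    np.maximum(a_new, 0.0, out=a_new)
    np.maximum(p_new, 0.0, out=p_new)
    return AgentPopulation(a=a_new, p=p_new, fitness=np.zeros(n))


# ---------------------------------------------------------------------------
# cultural processes
# ---------------------------------------------------------------------------


def displacements_all(log: CommunicationLog, params: SimParams
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-language displacement components, aligned with the log snapshot.

    Each distinct user *i* of language *x* contributes ``F / n_i`` to
    ``d_plus`` if its innate ability lies strictly above the language's
    position, or to ``d_minus`` (stored non-positive) if strictly below;
    users sitting exactly on the language contribute to neither.

    With ``params.displacement_weighting == "per_event"`` the sum runs over
    success incidences instead of distinct users, so heavy users pull
    proportionally harder.
    """
    nL = len(log.lang_positions)
    d_plus = np.zeros(nL)
    d_minus = np.zeros(nL)
    if nL == 0:
        return d_plus, d_minus
    if params.displacement_weighting == "per_event":
        ua = np.concatenate([log.pair_i, log.pair_j])
        ul = np.concatenate([log.pair_lang, log.pair_lang])
    else:
        ua, ul = log.user_incidence()
    if len(ua) == 0:
        return d_plus, d_minus
    w = params.F / log.usable_counts[ua]
    rel = log.agent_a[ua] - log.lang_positions[ul]
    above = rel > 0
    below = rel < 0
    d_plus += np.bincount(ul[above], weights=w[above], minlength=nL)
    d_minus += np.bincount(ul[below], weights=w[below], minlength=nL)
    return d_plus, -d_minus


def displacement(lang: Language, log: CommunicationLog, params: SimParams
                 ) -> tuple[float, float]:
    """``(d_plus, d_minus)`` for one language; ``(0, 0)`` if it has no users."""
    matches = np.nonzero(log.lang_lineages == lang.lineage_id)[0]
    if len(matches) == 0:
        return (0.0, 0.0)
    d_plus, d_minus = displacements_all(log, params)
    k = int(matches[0])
    return (float(d_plus[k]), float(d_minus[k]))


def apply_cultural_change(
    langs: LanguagePopulation,
    log: CommunicationLog,
    params: SimParams,
    generation: int = 0,
) -> tuple[LanguagePopulation, list[CulturalEvent]]:
    """Single displacement pass: each language either divides or moves.

    Division fires when ``min(d_plus, |d_minus|) > Fd``: the parent is
    removed and two children are placed at ``pos + d_plus`` and
    ``pos + d_minus`` under fresh lineage ids.  Otherwise the language moves
    by ``d_plus + d_minus`` (a change event is emitted only for a nonzero
    net move).  Positions are clamped at 0.
    """
    if not np.array_equal(langs.lineage_ids, log.lang_lineages):
        raise ValueError("log does not correspond to this language population")
    d_plus, d_minus = displacements_all(log, params)
    events: list[CulturalEvent] = []
    new_pos: list[float] = []
    new_ids: list[int] = []
    next_id = langs.next_id
    for k in range(len(langs)):
        pos = float(langs.positions[k])
        lid = int(langs.lineage_ids[k])
        dp, dm = float(d_plus[k]), float(d_minus[k])
        if min(dp, -dm) > params.Fd:
            child_hi = max(pos + dp, 0.0)
            child_lo = max(pos + dm, 0.0)
            ids = (next_id, next_id + 1)
            next_id += 2
            events.append(CulturalEvent(
                kind="division", generation=generation,
                parent_positions=(pos,), child_positions=(child_hi, child_lo),
                parent_lineages=(lid,), child_lineages=ids,
            ))
            new_pos.extend([child_hi, child_lo])
            new_ids.extend(ids)
        else:
            moved = max(pos + dp + dm, 0.0)
            if moved != pos:
                events.append(CulturalEvent(
                    kind="change", generation=generation,
                    parent_positions=(pos,), child_positions=(moved,),
                    parent_lineages=(lid,), child_lineages=(lid,),
                ))
            new_pos.append(moved)
            new_ids.append(lid)
    return LanguagePopulation(new_pos, new_ids, next_id=next_id), events


def apply_extinction(
    langs: LanguagePopulation,
    log: CommunicationLog,
    generation: int = 0,
) -> tuple[LanguagePopulation, list[CulturalEvent]]:
    """Remove every language that appears in the log with zero users.

    Lineages absent from the log snapshot (this generation's division
    children) are exempt.
    """
    counts = log.user_counts()
    used_lineages = set(log.lang_lineages[counts > 0].tolist())
    logged = set(log.lang_lineages.tolist())
    keep = np.array([
        (lid not in logged) or (lid in used_lineages)
        for lid in langs.lineage_ids
    ], dtype=bool)
    events = [
        CulturalEvent(
            kind="extinction", generation=generation,
            parent_positions=(float(pos),), child_positions=(),
            parent_lineages=(int(lid),), child_lineages=(),
        )
        for pos, lid, k in zip(langs.positions, langs.lineage_ids, keep)
        if not k
    ]
    return (
        LanguagePopulation(langs.positions[keep], langs.lineage_ids[keep],
                           next_id=langs.next_id),
        events,
    )


def apply_fusion(
    langs: LanguagePopulation,
    params: SimParams,
    generation: int = 0,
) -> tuple[LanguagePopulation, list[CulturalEvent]]:
    """Greedily merge the closest pair while its distance is below ``Tf``.

    The merged language sits at the parents' midpoint under a fresh lineage
    id; merging repeats (cascades included) until all pairwise distances are
    >= ``Tf``.  Ties on distance are broken toward the lower position.
    """
    pos = [float(x) for x in langs.positions]
    ids = [int(x) for x in langs.lineage_ids]
    next_id = langs.next_id
    events: list[CulturalEvent] = []
    while len(pos) >= 2:
        gaps = [pos[k + 1] - pos[k] for k in range(len(pos) - 1)]
        k = int(np.argmin(gaps))  # first occurrence = lowest position on ties
        if gaps[k] >= params.Tf:
            break
        mid = 0.5 * (pos[k] + pos[k + 1])
        events.append(CulturalEvent(
            kind="fusion", generation=generation,
            parent_positions=(pos[k], pos[k + 1]), child_positions=(mid,),
            parent_lineages=(ids[k], ids[k + 1]), child_lineages=(next_id,),
        ))
        pos[k:k + 2] = [mid]
        ids[k:k + 2] = [next_id]
        next_id += 1
    return LanguagePopulation(pos, ids, next_id=next_id), events


# ---------------------------------------------------------------------------
# generation step and full run
# ---------------------------------------------------------------------------


def step_generation(
    state: SimState,
    params: SimParams,
    rng: np.random.Generator,
    pair_idx: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[SimState, dict, list[CulturalEvent]]:
    """Advance one generation and return (new state, trace row, events).

    Order: communication -> fitness -> reproduction -> cultural change +
    division -> extinction -> fusion.  An empty language population is legal
    (a stagnant round with no successes) and the run continues.
    """
    gen = state.generation
    log = run_communication_round(state.agents, state.langs, rng, pair_idx=pair_idx)
    fitness = compute_fitness_all(state.agents, log, params)
    state.agents.fitness = fitness
    offspring = reproduce(state.agents, fitness, params, rng)
    langs, ev_change = apply_cultural_change(state.langs, log, params, generation=gen)
    langs, ev_ext = apply_extinction(langs, log, generation=gen)
    langs, ev_fus = apply_fusion(langs, params, generation=gen)
    events = ev_change + ev_ext + ev_fus
    row = {
        "gen": gen,
        "mean_a": float(np.mean(offspring.a)),
        "mean_p": float(np.mean(offspring.p)),
        "mean_fitness": float(np.mean(fitness)),
        "mean_lang_pos": langs.mean_position(),
        "n_langs": len(langs),
        "n_successes": log.n_successes,
    }
    return SimState(agents=offspring, langs=langs, generation=gen + 1), row, events


def run_simulation(
    params: SimParams,
    stop_on_extinction: bool = False,
    snapshots_every: int | None = None,
) -> RunTrace:
    """Run a full seeded simulation and return its :class:`RunTrace`.

    Initial state: ``a`` then ``p`` for all agents, then the initial
    language positions, all i.i.d. uniform on [0, 1] from the run RNG.
    With ``stop_on_extinction`` the loop ends right after the first
    generation whose language population is empty (the trace is then
    shorter than ``params.generations``).
    """
    rng = np.random.default_rng(params.seed)
    agents = AgentPopulation.random(params.N, rng)
    langs = LanguagePopulation.random(params.init_num_languages, rng)
    state = SimState(agents=agents, langs=langs, generation=0)
    pair_idx = _pair_indices(params.N)

    rows: list[dict] = []
    events: list[CulturalEvent] = []
    snapshots: dict[int, dict] = {}
    extinct_at: int | None = None
    for _ in range(params.generations):
        state, row, ev = step_generation(state, params, rng, pair_idx=pair_idx)
        rows.append(row)
        events.extend(ev)
        if snapshots_every and row["gen"] % snapshots_every == 0:
            snapshots[row["gen"]] = {
                "a": state.agents.a.copy(),
                "p": state.agents.p.copy(),
                "lang_positions": state.langs.positions.copy(),
            }
        if extinct_at is None and row["n_langs"] == 0:
            extinct_at = row["gen"]
            if stop_on_extinction:
                break
    df_cols = {c: np.array([r[c] for r in rows]) for c in RunTrace.COLUMNS}
    return RunTrace(
        params=params,
        events=events,
        total_extinction_generation=extinct_at,
        snapshots=snapshots,
        **df_cols,
    )
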