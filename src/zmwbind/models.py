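"""Candidate kinetic schemes for single-site ligand binding.

A :class:`KineticModel` is an aggregated continuous-time Markov chain whose
states carry a class tag (``unbound`` or ``bound``).  Binding transitions are
pseudo-first-order: their effective rate is ``k_on * [ligand]`` with ``k_on``
in M^-1 s^-1, while all other transitions are concentration-independent
conformational steps in s^-1.

Seven presets (models 1-7) describe the candidate schemes for cyclic
nucleotide association at HCN2 cyclic-nucleotide-binding domains, ranging
from a single binding step (model 1) to a linear six-state chain with
isomerization of both the apo and the ligand-bound domain (model 7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.linalg import null_space
from scipy.optimize import brentq
from scipy.sparse.csgraph import connected_components

UNBOUND = "unbound"
BOUND = "bound"

#: default box constraints for rate optimization, natural units
RATE_BOUNDS = (1e-4, 1e8)


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    rate_name: str
    is_binding: bool


@dataclass
class KineticModel:
    """State/transition topology with rate constants.

    Parameters
    ----------
    model_id : int
        Identifier of the scheme (presets use 1-7).
    states : list of (label, class) tuples
        Ordered state labels; class is ``"unbound"`` or ``"bound"``.
    transitions : list of Transition
    rate_values : dict
        Map rate-parameter name -> nonnegative rate.  M^-1 s^-1 for binding
        transitions, s^-1 otherwise.
    """

    model_id: int
    states: list[tuple[str, str]]
    transitions: list[Transition]
    rate_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [s for s, _ in self.states]
        classes = {s: c for s, c in self.states}
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate state labels")
        for c in classes.values():
            if c not in (UNBOUND, BOUND):
                raise ValueError(f"state class must be {UNBOUND!r} or {BOUND!r}, got {c!r}")
        present = set(classes.values())
        if present != {UNBOUND, BOUND}:
            raise ValueError("model needs at least one unbound and one bound state")
        for t in self.transitions:
            if t.source not in classes or t.target not in classes:
                raise ValueError(f"transition {t.rate_name}: endpoint not in states")
            should_bind = classes[t.source] == UNBOUND and classes[t.target] == BOUND
            if t.is_binding != should_bind:
                raise ValueError(
                    f"transition {t.source}->{t.target}: is_binding must be "
                    f"{should_bind} (unbound->bound transitions bind, others do not)"
                )
        for t in self.transitions:
            v = self.rate_values.get(t.rate_name)
            if v is None:
                raise ValueError(f"missing rate value for {t.rate_name}")
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"rate {t.rate_name} must be finite and >= 0, got {v}")

    # -- convenience views -------------------------------------------------
    @property
    def state_labels(self) -> list[str]:
        return [s for s, _ in self.states]

    @property
    def state_classes(self) -> dict[str, str]:
        return {s: c for s, c in self.states}

    def class_mask(self, cls: str) -> np.ndarray:
        return np.array([c == cls for _, c in self.states])

    @property
    def rate_names(self) -> list[str]:
        return [t.rate_name for t in self.transitions]

    def with_rates(self, rate_values: dict[str, float]) -> "KineticModel":
        return replace(self, rate_values=dict(rate_values))


@dataclass
class GeneratorMatrix:
    """Infinitesimal generator of a model at a fixed ligand concentration."""

    Q: np.ndarray
    state_order: list[str]
    concentration: float

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 2 or self.Q.shape[0] != self.Q.shape[1]:
            raise ValueError("Q must be square")


# ---------------------------------------------------------------------------
# presets


def _preset_dir():
    return resources.files("zmwbind") / "presets"


def load_model(path) -> KineticModel:
    """Load a model from a structured-text (YAML) specification file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    states = [(s["label"], s["class"]) for s in doc["states"]]
    transitions = []
    rates = {}
    for t in doc["transitions"]:
        transitions.append(
            Transition(t["from"], t["to"], t["rate"], bool(t["binding"]))
        )
        rates[t["rate"]] = float(t["value"])
    return KineticModel(int(doc["model_id"]), states, transitions, rates)


def table1_preset(model_id: int) -> KineticModel:
    """Return preset scheme ``model_id`` with its optimized rate constants."""
    if model_id not in range(1, 8):
        raise ValueError(f"unknown model_id {model_id}: valid ids are 1..7")
    ref = _preset_dir() / f"model{model_id}.yaml"
    with resources.as_file(ref) as path:
        return load_model(path)


# ---------------------------------------------------------------------------
# generator and analytic oracles


def build_generator(model: KineticModel, concentration: float) -> GeneratorMatrix:
    """Realize the scheme as a Q-matrix at ``concentration`` (molar)."""
    if not math.isfinite(concentration) or concentration < 0:
        raise ValueError(f"concentration must be finite and >= 0, got {concentration}")
    labels = model.state_labels
    idx = {s: i for i, s in enumerate(labels)}
    n = len(labels)
    Q = np.zeros((n, n))
    for t in model.transitions:
        rate = model.rate_values[t.rate_name]
        if t.is_binding:
            rate = rate * concentration
        Q[idx[t.source], idx[t.target]] += rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return GeneratorMatrix(Q, labels, concentration)


def _is_irreducible(Q: np.ndarray) -> bool:
    adj = (Q > 0).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    return n_comp == 1


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Least-squares stationary vector (valid also for reducible chains with
    a unique closed communicating class)."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def equilibrium_distribution(gen: GeneratorMatrix) -> np.ndarray:
    """Equilibrium probabilities pi with pi Q = 0, sum(pi) = 1.

    Raises
    ------
    ValueError
        If the chain is reducible at this concentration (e.g. a binding-only
        model at zero ligand), where no unique positive equilibrium exists.
    """
    if not _is_irreducible(gen.Q):
        raise ValueError(
            f"generator is reducible at concentration {gen.concentration:g} M; "
            "equilibrium distribution is not unique/positive"
        )
    ns = null_space(gen.Q.T)
    if ns.shape[1] != 1:
        raise ValueError("generator nullspace is not one-dimensional")
    pi = np.abs(ns[:, 0])
    return pi / pi.sum()


def bound_fraction(model: KineticModel, concentration: float) -> float:
    """Equilibrium probability of the bound class at a concentration."""
    gen = build_generator(model, concentration)
    pi = equilibrium_distribution(gen)
    return float(pi[model.class_mask(BOUND)].sum())


def class_entry_distribution(
    model: KineticModel, concentration: float, cls: str
) -> np.ndarray:
    """Stationary distribution over class states at the moment of entry."""
    gen = build_generator(model, concentration)
    pi = equilibrium_distribution(gen)
    mask = model.class_mask(cls)
    flux = pi[~mask] @ gen.Q[np.ix_(~mask, mask)]
    total = flux.sum()
    if total <= 0:
        raise ValueError(f"class {cls!r} is unreachable at {concentration:g} M")
    return flux / total


def mean_class_sojourn(model: KineticModel, concentration: float, cls: str) -> float:
    """Expected time from entering class ``cls`` until first exit.

    Solves the first-passage linear system (-Q_cc) t = 1 on the class
    sub-generator and averages over the stationary entry distribution.
    """
    if cls not in (UNBOUND, BOUND):
        raise ValueError(f"class must be {UNBOUND!r} or {BOUND!r}")
    mask = model.class_mask(cls)
    if not mask.any():
        raise ValueError(f"class {cls!r} is empty")
    gen = build_generator(model, concentration)
    entry = class_entry_distribution(model, concentration, cls)
    Qcc = gen.Q[np.ix_(mask, mask)]
    t = np.linalg.solve(-Qcc, np.ones(mask.sum()))
    return float(entry @ t)


def apparent_kd(model: KineticModel, c_max: float = 1.0) -> float:
    """Half-saturation ligand concentration of the equilibrium binding curve.

    The saturating bound probability is evaluated at ``c_max`` (default 1 M,
    far above any micromolar-affinity half-point); the half-saturation point
    is then located by root bracketing on the analytic occupancy curve.
    """
    b_sat = bound_fraction(model, c_max)
    grid = np.geomspace(1e-12, c_max, 200)
    occ = np.array([bound_fraction(model, c) for c in grid])
    if np.any(np.diff(occ) < -1e-10):
        raise ValueError("equilibrium occupancy is not monotone in concentration")
    target = 0.5 * b_sat
    return float(brentq(lambda c: bound_fraction(model, c) - target, 1e-12, c_max))
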