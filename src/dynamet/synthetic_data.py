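"""Simulation of dynamic-metabolomics cohorts from kinetic ODE systems.

A cohort is a set of subjects, each simulated from its own realization of a
kinetic model. Two sources of variation are injected on top of the reference
parameter set:

* **individual variation** (level ``beta``): every perturbable kinetic
  parameter of a subject is multiplied by ``1 + u`` with
  ``u ~ Uniform(-beta, beta)``, drawn independently per parameter and per
  subject — random biological variability;
* **induced variation** (level ``alpha``): a named kinetic parameter is
  decreased by the fraction ``alpha`` for every subject of a group — a mutant
  or treatment effect shared within that group.

Trajectories are stacked into a subjects x metabolites x time tensor
(:class:`MetabolomicsTensor`), optionally corrupted with homoscedastic
Gaussian noise of controlled relative magnitude and/or masked to emulate
missing measurements.

Two kinds of kinetic model are supported: the built-in linear open system
(:class:`LinearSystemSpec`, an 11-metabolite chain ``dx/dt = A x + b`` with a
tridiagonal mass-conserving rate matrix) and arbitrary user-registered
:class:`KineticSystem` plug-ins with a Python right-hand side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import root

__all__ = [
    "KineticSystem",
    "LinearSystemSpec",
    "VariationSpec",
    "GroupSpec",
    "CohortConfig",
    "MetabolomicsTensor",
    "default_linear_system",
    "degenerate_linear_system",
    "perturb_parameters",
    "apply_induced_variation",
    "simulate",
    "steady_state",
    "linear_time_grid",
    "cholesterol_time_grid",
    "generate_cohort",
    "add_noise",
    "make_missing_mask",
    "register_kinetic_model",
    "get_kinetic_model",
    "available_kinetic_models",
]


# --------------------------------------------------------------------------
# kinetic systems
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticSystem:
    """A kinetic ODE model ``dx/dt = rhs(x, params)`` with named parameters.

    ``rhs`` must return a vector of the same length as ``x0``. Every
    parameter that individual variation should perturb lives in ``params``;
    the right-hand side reads its values from the mapping it is handed.
    """

    rhs: Callable[[np.ndarray, Mapping[str, float]], np.ndarray]
    params: Mapping[str, float]
    x0: np.ndarray
    metabolite_names: tuple[str, ...]

    def __post_init__(self) -> None:
        x0 = np.asarray(self.x0, dtype=float)
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(self, "metabolite_names", tuple(self.metabolite_names))
        if len(self.metabolite_names) != x0.size:
            raise ValueError("metabolite_names length must match x0")
        out = np.asarray(self.rhs(x0, self.params), dtype=float)
        if out.shape != x0.shape:
            raise ValueError(
                f"rhs returns length {out.shape}, expected {x0.shape}"
            )


@dataclass(frozen=True)
class LinearSystemSpec:
    """Linear open system ``dx/dt = A x + b`` with a tridiagonal rate matrix.

    Only the off-diagonal rates (``sub``, ``sup``), the influx ``b`` and the
    initial state are free. Diagonal entries of columns 1..J-1 are derived so
    that each of those columns sums to zero (mass conservation: everything
    flowing out of a metabolite flows into a neighbour), while the last
    diagonal entry ``last_diag`` is pinned — it encodes the efflux that makes
    the system open.
    """

    sub: np.ndarray          # J-1 subdiagonal rates A[j+1, j], strictly positive
    sup: np.ndarray          # J-1 superdiagonal rates A[j, j+1], strictly positive
    b: np.ndarray            # influx, length J
    x0: np.ndarray           # initial concentrations, length J
    last_diag: float = -1.0e3
    metabolite_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sub = np.asarray(self.sub, dtype=float)
        sup = np.asarray(self.sup, dtype=float)
        b = np.asarray(self.b, dtype=float)
        x0 = np.asarray(self.x0, dtype=float)
        if sub.shape != sup.shape or sub.ndim != 1:
            raise ValueError("sub and sup must be 1-d arrays of equal length")
        if b.size != sub.size + 1 or x0.size != b.size:
            raise ValueError("b and x0 must have length len(sub) + 1")
        if np.any(sub <= 0) or np.any(sup <= 0):
            raise ValueError("off-diagonal rates must be strictly positive")
        names = self.metabolite_names or tuple(f"M{j + 1}" for j in range(b.size))
        if len(names) != b.size:
            raise ValueError("metabolite_names length must match system size")
        object.__setattr__(self, "sub", sub)
        object.__setattr__(self, "sup", sup)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "metabolite_names", names)

    @property
    def n_metabolites(self) -> int:
        return self.b.size

    @property
    def A(self) -> np.ndarray:
        """Assemble the tridiagonal rate matrix with derived diagonals."""
        J = self.n_metabolites
        A = np.zeros((J, J))
        A[np.arange(1, J), np.arange(J - 1)] = self.sub
        A[np.arange(J - 1), np.arange(1, J)] = self.sup
        # zero column sums for all but the last column
        for j in range(J - 1):
            A[j, j] = -(A[:, j].sum() - A[j, j])
        A[J - 1, J - 1] = self.last_diag
        return A


def default_linear_system() -> LinearSystemSpec:
    """The reference 11-metabolite linear open chain.

    Influx 100 into the first metabolite; sub-/superdiagonal exchange rates of
    order 1e2-3e3 per minute; unit initial concentrations. Columns 1-10 of the
    rate matrix sum to zero and A(11,11) = -1000 fixes the efflux.
    """
    sub = 1e3 * np.array([0.2, 0.1, 0.5, 0.3, 2, 1, 3, 0.4, 1, 0.4])
    sup = 1e3 * np.array([0.3, 0.5, 2, 2, 0.3, 3, 0.5, 1, 0.2, 0.4])
    b = 1e3 * np.array([0.1] + [0.0] * 10)
    return LinearSystemSpec(sub=sub, sup=sup, b=b, x0=np.ones(11), last_diag=-1e3)


def degenerate_linear_system() -> LinearSystemSpec:
    """Variant chain with uniform exchange rates (all off-diagonals 1000).

    With the derived diagonals this reproduces diag = 1e3*[-1, -2, ..., -2];
    a small-individual-variation cohort from this system drives the
    2-component CP model into two-factor degeneracy.
    """
    ones = 1e3 * np.ones(10)
    b = 1e3 * np.array([0.5] + [0.0] * 10)
    return LinearSystemSpec(sub=ones, sup=ones, b=b, x0=np.ones(11), last_diag=-2e3)


# --------------------------------------------------------------------------
# variation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariationSpec:
    """Individual-variation level and the induced parameter knock-downs of a group.

    ``init_from_steady_state`` makes subjects of the group start from the
    *unmodified* model's steady state instead of its nominal initial
    condition — the usual convention for mutant subjects of plug-in models.
    """

    beta: float = 0.0
    induced: tuple[tuple[str, float], ...] = ()
    init_from_steady_state: bool = False

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        induced = tuple((str(p), float(a)) for p, a in self.induced)
        for p, a in induced:
            if not 0 <= a < 1:
                raise ValueError(f"alpha for {p!r} must be in [0, 1), got {a}")
        object.__setattr__(self, "induced", induced)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_subjects: int
    variation: VariationSpec

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one simulated dataset: groups, sampling times, seed."""

    groups: tuple[GroupSpec, ...]
    time_grid: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        t = np.asarray(self.time_grid, dtype=float)
        if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time_grid must be 1-d and strictly increasing")
        object.__setattr__(self, "time_grid", t)

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)

    @staticmethod
    def from_dict(d: Mapping) -> "CohortConfig":
        groups = tuple(
            GroupSpec(
                label=g["label"],
                n_subjects=int(g["n"]),
                variation=VariationSpec(
                    beta=float(g.get("beta", 0.0)),
                    induced=tuple(
                        (iv["param"], float(iv["alpha"]))
                        for iv in g.get("induced", [])
                    ),
                    init_from_steady_state=bool(g.get("init_from_steady_state", False)),
                ),
            )
            for g in d["groups"]
        )
        return CohortConfig(groups=groups, time_grid=np.asarray(d["time_grid"], float),
                            seed=int(d["seed"]))

    @staticmethod
    def from_yaml(path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            return CohortConfig.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "groups": [
                {
                    "label": g.label,
                    "n": g.n_subjects,
                    "beta": g.variation.beta,
                    "induced": [
                        {"param": p, "alpha": a} for p, a in g.variation.induced
                    ],
                    "init_from_steady_state": g.variation.init_from_steady_state,
                }
                for g in self.groups
            ],
            "time_grid": [float(t) for t in self.time_grid],
            "seed": self.seed,
        }


# --------------------------------------------------------------------------
# the tensor container
# --------------------------------------------------------------------------

@dataclass
class MetabolomicsTensor:
    """Subjects x metabolites x time data cube with mode labels.

    ``mask`` (if present) is the binary observation array W: 1 = measured,
    0 = missing.
    """

    values: np.ndarray
    subject_groups: tuple[str, ...]
    metabolite_names: tuple[str, ...]
    times: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.subject_groups = tuple(self.subject_groups)
        self.metabolite_names = tuple(self.metabolite_names)
        I, J, K = self.values.shape
        if len(self.subject_groups) != I:
            raise ValueError("subject_groups length must equal axis 0")
        if len(self.metabolite_names) != J:
            raise ValueError("metabolite_names length must equal axis 1")
        if self.times.size != K:
            raise ValueError("times length must equal axis 2")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must equal values shape")
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask entries must be 0 or 1")
            if not np.isfinite(self.values[self.mask.astype(bool)]).all():
                raise ValueError("non-finite value at an observed entry")
        elif not np.isfinite(self.values).all():
            raise ValueError("non-finite value in tensor")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long-format (subject, group, metabolite, time, value[, observed]) table."""
        I, J, K = self.shape
        idx = np.indices((I, J, K)).reshape(3, -1)
        df = pd.DataFrame(
            {
                "subject": idx[0] + 1,
                "group": np.asarray(self.subject_groups)[idx[0]],
                "metabolite": np.asarray(self.metabolite_names)[idx[1]],
                "time": self.times[idx[2]],
                "value": self.values.ravel(),
            }
        )
        if self.mask is not None:
            df["observed"] = self.mask.ravel().astype(int)
        return df

    def save(self, path) -> None:
        """Write to an HDF5 container with named dimension scales."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=self.values)
            fh.create_dataset("subject_groups",
                              data=np.array(self.subject_groups, dtype="S"))
            fh.create_dataset("metabolite_names",
                              data=np.array(self.metabolite_names, dtype="S"))
            fh.create_dataset("times", data=self.times)
            if self.mask is not None:
                fh.create_dataset("mask", data=self.mask.astype(np.int8))
            fh["values"].attrs["dims"] = "subjects,metabolites,time"

    @staticmethod
    def load(path) -> "MetabolomicsTensor":
        import h5py

        with h5py.File(path, "r") as fh:
            return MetabolomicsTensor(
                values=fh["values"][...],
                subject_groups=tuple(s.decode() for s in fh["subject_groups"][...]),
                metabolite_names=tuple(s.decode() for s in fh["metabolite_names"][...]),
                times=fh["times"][...],
                mask=fh["mask"][...] if "mask" in fh else None,
            )


# --------------------------------------------------------------------------
# parameter variation operators
# --------------------------------------------------------------------------

def perturb_parameters(system, beta: float, rng: np.random.Generator):
    """Multiply every perturbable parameter by ``1 + u``, ``u ~ U(-beta, beta)``.

    For :class:`LinearSystemSpec` the perturbable parameters are the sub- and
    superdiagonal rates; diagonals are re-derived by the spec itself, so mass
    conservation (zero column sums) holds for the perturbed subject as well.
    For a generic :class:`KineticSystem` every entry of ``params`` is
    perturbed.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if isinstance(system, LinearSystemSpec):
        n = system.sub.size
        u = rng.uniform(-beta, beta, size=2 * n)
        return replace(system, sub=system.sub * (1 + u[:n]), sup=system.sup * (1 + u[n:]))
    if isinstance(system, KineticSystem):
        keys = sorted(system.params)
        u = rng.uniform(-beta, beta, size=len(keys))
        new = {k: system.params[k] * (1 + ui) for k, ui in zip(keys, u)}
        return replace(system, params=new)
    raise TypeError(f"unsupported system type {type(system).__name__}")


_PARAM_RE = re.compile(r"^A\((\d+),(\d+)\)$")


def apply_induced_variation(system, param_id: str, alpha: float):
    """Decrease one named kinetic parameter by the fraction ``alpha``.

    Linear-system parameters are addressed in 1-based matrix notation,
    e.g. ``"A(7,6)"`` for the rate from metabolite 6 to metabolite 7 (a
    subdiagonal entry). Diagonals are re-derived afterwards, so the mass
    constraint still holds for the modified subject.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    if isinstance(system, LinearSystemSpec):
        m = _PARAM_RE.match(param_id.replace(" ", ""))
        if not m:
            raise KeyError(
                f"unknown parameter {param_id!r}; expected 'A(i,j)' with |i-j| = 1"
            )
        i, j = int(m.group(1)), int(m.group(2))
        J = system.n_metabolites
        if not (1 <= i <= J and 1 <= j <= J):
            raise KeyError(f"{param_id!r} outside the {J}x{J} rate matrix")
        if i == j + 1:      # subdiagonal A[j+1, j]
            sub = system.sub.copy()
            sub[j - 1] *= 1 - alpha
            return replace(system, sub=sub)
        if j == i + 1:      # superdiagonal A[i, i+1]
            sup = system.sup.copy()
            sup[i - 1] *= 1 - alpha
            return replace(system, sup=sup)
        raise KeyError(f"{param_id!r} is not an off-diagonal rate")
    if isinstance(system, KineticSystem):
        if param_id not in system.params:
            raise KeyError(f"unknown parameter {param_id!r}")
        new = dict(system.params)
        new[param_id] *= 1 - alpha
        return replace(system, params=new)
    raise TypeError(f"unsupported system type {type(system).__name__}")


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def simulate(system, times: Sequence[float], x0: np.ndarray | None = None) -> np.ndarray:
    """Solve the system from ``x0`` at t=0 and sample at ``times``.

    Returns a metabolites x time array. Linear systems use the closed form
    ``x(t) = x_ss + e^{At}(x0 - x_ss)`` with ``x_ss = -A^{-1} b``; generic
    systems are integrated with a stiff-capable adaptive solver
    (rtol 1e-8, atol 1e-10) because kinetic rate constants commonly span
    several orders of magnitude.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be 1-d and strictly increasing")
    if times[0] < 0:
        raise ValueError("times must be non-negative")
    if x0 is None:
        x0 = system.x0
    x0 = np.asarray(x0, dtype=float)

    if isinstance(system, LinearSystemSpec):
        A, b = system.A, system.b
        x_ss = np.linalg.solve(A, -b)
        dev0 = x0 - x_ss
        out = np.empty((x0.size, times.size))
        for k, t in enumerate(times):
            out[:, k] = x_ss + expm(A * t) @ dev0
        return out

    if isinstance(system, KineticSystem):
        params = system.params

        def f(_t, x):
            return np.asarray(system.rhs(x, params), dtype=float)

        sol = solve_ivp(
            f, (0.0, float(times[-1])), x0, method="LSODA",
            t_eval=times, rtol=1e-8, atol=1e-10,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        return sol.y

    raise TypeError(f"unsupported system type {type(system).__name__}")


def steady_state(system) -> np.ndarray:
    """Steady state of the (unmodified) system.

    Linear systems solve ``A x + b = 0`` exactly; generic systems integrate
    long past the initial transient and polish with a root solve of the
    right-hand side.
    """
    if isinstance(system, LinearSystemSpec):
        return np.linalg.solve(system.A, -system.b)
    if isinstance(system, KineticSystem):
        params = system.params

        def f(_t, x):
            return np.asarray(system.rhs(x, params), dtype=float)

        sol = solve_ivp(f, (0.0, 1e4), system.x0, method="LSODA",
                        rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise RuntimeError(f"steady-state integration failed: {sol.message}")
        x_long = sol.y[:, -1]
        res = root(lambda x: np.asarray(system.rhs(x, params), float), x_long)
        return res.x if res.success else x_long
    raise TypeError(f"unsupported system type {type(system).__name__}")


# --------------------------------------------------------------------------
# sampling grids
# --------------------------------------------------------------------------

def linear_time_grid() -> np.ndarray:
    """Sampling times (6 + 5k) * 0.002 for k = 0..19: 0.012, 0.022, ..., 0.202."""
    return (6 + 5 * np.arange(20)) * 0.002


def cholesterol_time_grid() -> np.ndarray:
    """Every 24th point of the 1000-point grid logspace(0, 6, 1000) - 1, 21 points."""
    base = np.logspace(0, 6, 1000) - 1
    return base[::24][:21]


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, system) -> MetabolomicsTensor:
    """Simulate every subject of every group and stack the trajectories.

    Per-subject RNG streams are spawned from the config seed with one child
    sequence per group, then one grand-child per subject, so appending a new
    group (or adding subjects at the end of a group) never changes the
    subjects simulated before it. The result is a pure function of
    ``(config, system)``.
    """
    root_ss = np.random.SeedSequence(config.seed)
    group_seqs = root_ss.spawn(len(config.groups))
    slabs: list[np.ndarray] = []
    labels: list[str] = []
    ss_cache: np.ndarray | None = None
    for group, gseq in zip(config.groups, group_seqs):
        subj_seqs = gseq.spawn(group.n_subjects)
        x0 = None
        if group.variation.init_from_steady_state:
            if ss_cache is None:
                ss_cache = steady_state(system)
            x0 = ss_cache
        for s, sseq in enumerate(subj_seqs):
            rng = np.random.default_rng(sseq)
            subject_system = perturb_parameters(system, group.variation.beta, rng)
            for param_id, alpha in group.variation.induced:
                subject_system = apply_induced_variation(subject_system, param_id, alpha)
            try:
                traj = simulate(subject_system, config.time_grid, x0=x0)
            except Exception as exc:  # noqa: BLE001 - annotate which subject failed
                raise RuntimeError(
                    f"simulation failed for subject {s + 1} of group "
                    f"{group.label!r}: {exc}"
                ) from exc
            slabs.append(traj)
            labels.append(group.label)
    names = getattr(system, "metabolite_names", None) or tuple(
        f"M{j + 1}" for j in range(slabs[0].shape[0])
    )
    return MetabolomicsTensor(
        values=np.stack(slabs, axis=0),
        subject_groups=tuple(labels),
        metabolite_names=tuple(names),
        times=config.time_grid,
    )


# --------------------------------------------------------------------------
# noise and missingness
# --------------------------------------------------------------------------

def add_noise(X: np.ndarray, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Add Gaussian noise scaled so that ||X_noise - X|| / ||X|| equals ``eta``.

    X_noise = X + eta * N * ||X|| / ||N||  with N i.i.d. standard normal.
    A zero tensor is returned unchanged (the scale collapses).
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    X = np.asarray(X, dtype=float)
    norm_x = np.linalg.norm(X)
    if eta == 0 or norm_x == 0:
        return X.copy()
    N = rng.standard_normal(X.shape)
    return X + eta * N * (norm_x / np.linalg.norm(N))


def make_missing_mask(shape: tuple[int, ...], fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Binary observation mask with exactly round(fraction * size) zeros.

    Missing positions are drawn uniformly without replacement.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    size = int(np.prod(shape))
    n_missing = int(round(fraction * size))
    mask = np.ones(size, dtype=np.int8)
    if n_missing:
        mask[rng.choice(size, size=n_missing, replace=False)] = 0
    return mask.reshape(shape)


# --------------------------------------------------------------------------
# plug-in registry
# --------------------------------------------------------------------------

_MODEL_REGISTRY: dict[str, Callable[[], object]] = {
    "linear": default_linear_system,
    "linear_degenerate": degenerate_linear_system,
}


def register_kinetic_model(name: str, factory: Callable[[], object]) -> None:
    """Register a kinetic-model factory under ``name`` for config-driven runs.

    External published models (e.g. a glycolysis or whole-body cholesterol
    model) plug in here; their parameter sets are supplied by the user, not
    shipped with the package.
    """
    _MODEL_REGISTRY[str(name)] = factory


def get_kinetic_model(name: str):
    try:
        factory = _MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown kinetic model {name!r}; available: "
            f"{sorted(_MODEL_REGISTRY)}"
        ) from None
    return factory()


def available_kinetic_models() -> tuple[str, ...]:
    return tuple(sorted(_MODEL_REGISTRY))
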