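"""CPT estimation: smoothed relative frequencies and EM for incomplete data.

With complete data each CPT row is a smoothed relative frequency,
P(x | pa) = (N(x, pa) + c) / (N(pa) + c*K), where c is the pseudocount and
K the child's state count. With missing values the expectation-maximization
algorithm alternates an exact E-step (expected family counts given each
record's observed values) with the same M-step on expected counts.

A positive pseudocount corresponds to a Dirichlet(c+1) prior on every CPT
row, so EM here maximizes the penalized objective
log-likelihood + c * sum(log theta); that penalized objective — not the raw
likelihood — carries the EM monotonicity guarantee and is what
``FitResult.loglik_trace`` records (the two coincide at c = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import FullJoint
from .network import BayesianNetworkModel, CPTSet, NetworkStructure, uniform_cpts
from .questionnaire import DiscreteDataset

__all__ = ["FitResult", "encode_dataset", "ml_estimate", "em_fit"]


@dataclass
class FitResult:
    """Outcome of a parameter-learning run."""

    cpts: CPTSet
    loglik_trace: list[float]
    n_iterations: int
    converged: bool
    observed_loglik: float
    settings: dict = field(default_factory=dict)

    @property
    def model(self) -> BayesianNetworkModel:
        return BayesianNetworkModel(self.cpts.structure, self.cpts)


def encode_dataset(dataset: DiscreteDataset, structure: NetworkStructure) -> np.ndarray:
    """Integer-code a discrete dataset: (n, n_vars) with -1 for missing."""
    n = len(dataset)
    codes = np.full((n, len(structure.names)), -1, dtype=np.int64)
    for j, name in enumerate(structure.names):
        spec = structure[name]
        col = dataset.frame[name]
        for s_idx, label in enumerate(spec.states):
            codes[(col == label).to_numpy(), j] = s_idx
        bad = col.notna().to_numpy() & (codes[:, j] < 0)
        if bad.any():
            raise ValueError(
                f"illegal state(s) for {name!r}: {sorted(set(col[bad]))}"
            )
    return codes


def _family_indices(structure: NetworkStructure):
    """Per node: (child axis, parent axes, mixed-radix weights, n_cfg)."""
    axis = {name: i for i, name in enumerate(structure.names)}
    out = {}
    for name in structure.names:
        pars = structure.parents[name]
        weights = []
        w = 1
        for p in reversed(pars):
            weights.append(w)
            w *= structure[p].n_states
        weights.reverse()
        out[name] = (axis[name], [axis[p] for p in pars], np.array(weights, dtype=np.int64), w)
    return out


def _count_complete(structure, codes, counts):
    """Vectorized exact counting over fully observed rows."""
    fam = _family_indices(structure)
    for name in structure.names:
        child_ax, par_axes, weights, _ = fam[name]
        cfg = (
            codes[:, par_axes] @ weights if par_axes else
            np.zeros(len(codes), dtype=np.int64)
        )
        np.add.at(counts[name], (cfg, codes[:, child_ax]), 1.0)


def _loglik_complete(structure, codes, cpts) -> float:
    fam = _family_indices(structure)
    total = 0.0
    for name in structure.names:
        child_ax, par_axes, weights, _ = fam[name]
        cfg = (
            codes[:, par_axes] @ weights if par_axes else
            np.zeros(len(codes), dtype=np.int64)
        )
        total += float(np.log(cpts[name][cfg, codes[:, child_ax]]).sum())
    return total


def ml_estimate(
    structure: NetworkStructure,
    dataset: DiscreteDataset | np.ndarray,
    pseudocount: float = 1.0,
) -> CPTSet:
    """Smoothed relative-frequency CPTs from complete data.

    Parent configurations never seen in the data fall back to the smoothed
    uniform row (requires ``pseudocount > 0`` for them to be well-defined).
    """
    codes = dataset if isinstance(dataset, np.ndarray) else encode_dataset(dataset, structure)
    if (codes < 0).any():
        raise ValueError("ml_estimate requires complete data; use em_fit")
    counts = {
        name: np.zeros(structure.cpt_shape(name)) for name in structure.names
    }
    _count_complete(structure, codes, counts)
    return _m_step(structure, counts, pseudocount)


def _m_step(structure, counts, pseudocount) -> CPTSet:
    tables = {}
    for name, cnt in counts.items():
        k = cnt.shape[1]
        denom = cnt.sum(axis=1, keepdims=True) + pseudocount * k
        if pseudocount == 0:
            with np.errstate(invalid="ignore"):
                tab = cnt / denom
            tab[np.isnan(tab)] = 1.0 / k  # unseen configs: uniform fallback
        else:
            tab = (cnt + pseudocount) / denom
        tables[name] = tab
    return CPTSet(structure, tables)


def _penalty(cpts: CPTSet, pseudocount: float) -> float:
    if pseudocount == 0:
        return 0.0
    return pseudocount * sum(float(np.log(tab).sum()) for tab in cpts.values())


def _e_step(structure, joint: FullJoint, inc_codes, inc_weights, counts):
    """Expected family counts and observed log-likelihood for incomplete rows."""
    names = structure.names
    n_vars = len(names)
    fam = _family_indices(structure)
    loglik = 0.0
    for row, weight in zip(inc_codes, inc_weights):
        obs = {names[j]: int(row[j]) for j in range(n_vars) if row[j] >= 0}
        arr, free = joint._restrict(obs)
        z = arr.sum()
        if z <= 0.0:
            raise ValueError(f"record {dict(obs)} has probability 0 under current model")
        loglik += weight * np.log(z)
        w = arr / z
        free_pos = {name: i for i, name in enumerate(free)}
        for name in names:
            child_ax, par_axes, weights_mr, _ = fam[name]
            members = [*par_axes, child_ax]
            miss_members = [m for m in members if names[m] in free_pos]
            if not miss_members:
                cfg = int(sum(row[a] * wt for a, wt in zip(par_axes, weights_mr)))
                counts[name][cfg, row[child_ax]] += weight
                continue
            drop = tuple(
                i for i, fname in enumerate(free) if joint.axis[fname] not in miss_members
            )
            marg = w.sum(axis=drop) if drop else w
            # axes of marg follow `free` order restricted to miss_members
            marg_order = [joint.axis[f] for f in free if joint.axis[f] in miss_members]
            for idx in np.ndindex(marg.shape):
                states = dict(zip(marg_order, idx))
                full = [states.get(m, row[m]) for m in members]
                cfg = int(sum(s * wt for s, wt in zip(full[:-1], weights_mr)))
                counts[name][cfg, full[-1]] += weight * float(marg[idx])
    return loglik


def em_fit(
    structure: NetworkStructure,
    dataset: DiscreteDataset | np.ndarray,
    *,
    init: str = "uniform",
    pseudocount: float = 1.0,
    tolerance: float = 1e-6,
    max_iterations: int = 500,
    seed: int | None = None,
    jitter: float = 0.0,
) -> FitResult:
    """Fit CPTs by EM on a dataset that may contain missing values.

    The E-step conditions the exact joint on each record's observed states
    to obtain expected (parent configuration, child state) counts; the
    M-step re-estimates each row as a smoothed relative frequency of those
    expected counts. Iteration stops when the relative change of the
    penalized objective drops below ``tolerance`` or after
    ``max_iterations`` M-steps (reported via ``converged``).

    ``init='uniform'`` starts from uniform CPTs; ``init='random'`` (or a
    positive ``jitter`` with seeded randomness) draws Dirichlet rows for
    multi-start exploration. On complete data the first M-step reproduces
    :func:`ml_estimate` exactly and EM stops immediately after.
    """
    codes = dataset if isinstance(dataset, np.ndarray) else encode_dataset(dataset, structure)
    if codes.shape[0] == 0:
        raise ValueError("empty dataset")
    settings = dict(
        init=init, pseudocount=pseudocount, tolerance=tolerance,
        max_iterations=max_iterations, seed=seed, jitter=jitter,
    )

    if init == "uniform" and jitter == 0.0:
        cpts = uniform_cpts(structure)
    elif init in ("uniform", "random"):
        rng = np.random.default_rng(seed)
        conc = 1.0 / jitter if (init == "uniform" and jitter > 0) else 1.0
        tables = {}
        for name in structure.names:
            n_cfg, n_states = structure.cpt_shape(name)
            tables[name] = rng.dirichlet(np.full(n_states, conc), size=n_cfg)
        cpts = CPTSet(structure, tables)
    else:
        raise ValueError(f"unknown init mode {init!r}")

    complete_mask = (codes >= 0).all(axis=1)
    comp = codes[complete_mask]
    inc = codes[~complete_mask]
    # collapse duplicate incomplete rows; the E-step cost is per unique row
    if len(inc):
        inc_unique, inc_weights = np.unique(inc, axis=0, return_counts=True)
        inc_weights = inc_weights.astype(float)
    else:
        inc_unique, inc_weights = inc, np.zeros(0)

    trace: list[float] = []
    observed_ll = -np.inf
    converged = False
    iterations = 0
    for it in range(max_iterations + 1):
        model = BayesianNetworkModel(structure, cpts)
        counts = {name: np.zeros(structure.cpt_shape(name)) for name in structure.names}
        if len(comp):
            _count_complete(structure, comp, counts)
        ll = _loglik_complete(structure, comp, cpts) if len(comp) else 0.0
        if len(inc_unique):
            ll += _e_step(structure, FullJoint(model), inc_unique, inc_weights, counts)
        observed_ll = ll
        objective = ll + _penalty(cpts, pseudocount)
        trace.append(objective)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(objective - prev) <= tolerance * (abs(prev) + 1e-12):
                converged = True
                break
        if it == max_iterations:
            break
        cpts = _m_step(structure, counts, pseudocount)
        iterations += 1

    return FitResult(
        cpts=cpts,
        loglik_trace=trace,
        n_iterations=iterations,
        converged=converged,
        observed_loglik=observed_ll,
        settings=settings,
    )
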