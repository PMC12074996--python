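"""Physics-informed active learning for surface-hopping potentials.

The loop trains two multi-state models on the current data — a *main* model
(energies + forces + gaps) that drives the dynamics, and an *auxiliary*
model (energies only) whose disagreement with the main model,
U = |E_aux - E_main|, serves as the uncertainty metric.  Per-state UQ
thresholds are set once, from the initial validation set, as

    threshold_s = median(U_s) + 3 * MAD(U_s)

with the raw (unscaled) median absolute deviation, and are never revised.
Each ML-TSH step is screened in order: negative predicted gap, then
current-surface UQ, then adjacent-surface UQ; the first failure stops the
trajectory and samples that geometry.  Additional geometries come from
gap-driven trajectories spawned off the certain part of each TSH
trajectory, and from steps where the main- and auxiliary-model hopping
probabilities disagree by more than a tolerance (capped per iteration).
All sampled points are labeled by the reference and added to the training
set; the loop stops once the fraction of fully-certain TSH trajectories
reaches the convergence target (default 95%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .descriptors_model import (LossWeights, MultiStateModel, TrainConfig,
                                train)
from .gapmd import GapMDConfig, propagate_gapmd
from .initial_conditions import (InitialCondition, NormalModeData,
                                 filter_excitation_window, wigner_sample)
from .model_surfaces import eval_adiabatic
from .surface_hopping import (Trajectory, detect_gap_minimum, lz_probability,
                              propagate_tsh)
from .training_data import TrainingRecord, TrainingSet
from .units import INVCM_TO_AU, HARTREE_IN_INVCM, masses_au

logger = logging.getLogger(__name__)

__all__ = [
    "UQRecord",
    "UQThresholds",
    "ALConfig",
    "ALState",
    "ALMonitor",
    "threshold_from_deviations",
    "compute_thresholds",
    "check_step",
    "probability_uncertain_points",
    "spawn_gapmd",
    "broaden_training_set",
    "build_initial_set",
    "run_al",
]


@dataclass
class UQRecord:
    deviations: np.ndarray        # per-state U = |E_aux - E_main|, >= 0
    exceeded: np.ndarray          # per-state flags

    def __post_init__(self):
        self.deviations = np.asarray(self.deviations, dtype=float)
        if np.any(self.deviations < 0):
            raise ValueError("deviations must be non-negative")


@dataclass
class UQThresholds:
    thresholds: np.ndarray        # per-state, Hartree
    medians: np.ndarray
    mads: np.ndarray
    validation_id: str = ""

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.medians = np.asarray(self.medians, dtype=float)
        self.mads = np.asarray(self.mads, dtype=float)

    @property
    def n_states(self) -> int:
        return len(self.thresholds)


def threshold_from_deviations(u: np.ndarray) -> Tuple[float, float, float]:
    """(median, raw MAD, median + 3 MAD) of a deviation sample."""
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise ValueError("empty deviation sample")
    med = float(np.median(u))
    mad = float(np.median(np.abs(u - med)))
    return med, mad, med + 3.0 * mad


def compute_thresholds(main: MultiStateModel, aux: MultiStateModel,
                       validation_geometries: Sequence[np.ndarray],
                       elements, n_states: Optional[int] = None,
                       validation_id: str = "") -> UQThresholds:
    """Per-state UQ thresholds median + 3 MAD over a validation set."""
    geometries = list(validation_geometries)
    if not geometries:
        raise ValueError("empty validation set")
    if n_states is None:
        n_states = main.n_states_trained
    states = list(range(n_states))
    u = np.array(
        [
            np.abs(
                np.asarray(aux.predict_states(g, elements, states))
                - np.asarray(main.predict_states(g, elements, states))
            )
            for g in geometries
        ]
    )
    med, mad, thr = zip(*(threshold_from_deviations(u[:, s])
                          for s in range(n_states)))
    return UQThresholds(
        thresholds=np.array(thr), medians=np.array(med), mads=np.array(mad),
        validation_id=validation_id,
    )


def check_step(energies_main, energies_aux, j: int,
               thresholds: UQThresholds) -> str:
    """Step verdict, first failing criterion wins.

    Order: negative gap to either neighbor of the active state ``j``, then
    UQ of the current surface, then UQ of the adjacent surfaces.
    """
    e = np.asarray(energies_main, dtype=float)
    n = len(e)
    if not 0 <= j < n:
        raise ValueError(f"active state {j} out of range")
    if (j + 1 < n and e[j + 1] - e[j] < 0) or (j > 0 and e[j] - e[j - 1] < 0):
        return "negative_gap"
    u = np.abs(np.asarray(energies_aux, dtype=float) - e)
    thr = thresholds.thresholds
    if u[j] > thr[j]:
        return "uncertain_current"
    for k in (j - 1, j + 1):
        if 0 <= k < n and u[k] > thr[k]:
            return "uncertain_adjacent"
    return "ok"


class ALMonitor:
    """Per-step screen used by monitored TSH / gapMD propagation."""

    def __init__(self, aux_potential, thresholds: UQThresholds):
        self.aux_potential = aux_potential
        self.thresholds = thresholds

    def aux_energies(self, coords) -> np.ndarray:
        return self.aux_potential.energies(coords)

    def check(self, energies_main, energies_aux, j: int) -> str:
        return check_step(energies_main, energies_aux, j, self.thresholds)


def probability_uncertain_points(
    trajectories, tol: float = 0.10, cap: int = 15, seed: int = 0,
) -> List[np.ndarray]:
    """Geometries where main/aux hopping probabilities disagree.

    LZBL probabilities are evaluated at every strict minimum of the
    main-model gap between the active state and each adjacent state, from
    both the main and the auxiliary gap histories; steps where they differ
    by more than ``tol`` are flagged, and at most ``cap`` flagged
    geometries are drawn uniformly without replacement.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    flagged = []
    for traj in trajectories:
        if traj.aux_energies is None or len(traj) < 3:
            continue
        dt = traj.dt
        e_m, e_a = traj.energies, traj.aux_energies
        act = traj.active_state
        for i in range(1, len(traj) - 1):
            j = act[i]
            if act[i - 1] != j or act[i + 1] != j:
                continue  # no clean three-point window across a hop
            for k in (j - 1, j + 1):
                if not 0 <= k < e_m.shape[1]:
                    continue
                zm = np.abs(e_m[i - 1 : i + 2, k] - e_m[i - 1 : i + 2, j])
                is_min, zdd_m = detect_gap_minimum(zm[0], zm[1], zm[2], dt)
                if not is_min:
                    continue
                p_main = lz_probability(zm[1], zdd_m)
                za = np.abs(e_a[i - 1 : i + 2, k] - e_a[i - 1 : i + 2, j])
                _, zdd_a = detect_gap_minimum(za[0], za[1], za[2], dt)
                p_aux = lz_probability(za[1], zdd_a) if zdd_a > 0 else 0.0
                if abs(p_main - p_aux) > tol:
                    flagged.append(traj.coords[i].copy())
    if len(flagged) <= cap:
        return flagged
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(flagged), size=cap, replace=False)
    return [flagged[i] for i in sorted(keep)]


def _certain_steps(traj: Trajectory) -> int:
    """Number of leading steps not flagged by any criterion."""
    if traj.verdict == "completed":
        return len(traj)
    return traj.stop_step if traj.stop_step is not None else len(traj)


def spawn_gapmd(
    tsh_trajectories: Sequence[Trajectory],
    n_states: int,
    seed: int = 0,
) -> List[Tuple[InitialCondition, Tuple[int, int], str]]:
    """GapMD initial conditions off the certain part of TSH trajectories.

    One seeded-random certain step per trajectory becomes an initial
    condition; the adjacent state pair is drawn uniformly; branches are
    split half upper / half lower across the batch.
    """
    rng = np.random.default_rng(seed)
    picks = []
    for traj in tsh_trajectories:
        n_ok = _certain_steps(traj)
        if n_ok < 1:
            logger.info("TSH trajectory uncertain at step 0; gapMD spawn skipped")
            continue
        i = int(rng.integers(n_ok))
        lo = int(rng.integers(n_states - 1))
        picks.append(
            (
                InitialCondition(
                    coords=traj.coords[i].copy(),
                    velocities=traj.velocities[i].copy(),
                    state=int(traj.active_state[i]),
                ),
                (lo, lo + 1),
            )
        )
    order = rng.permutation(len(picks))
    n_upper = len(picks) // 2
    out = []
    for rank, idx in enumerate(np.argsort(order)):
        branch = "upper" if rank < n_upper else "lower"
        ic, pair = picks[idx]
        out.append((ic, pair, branch))
    return out


def broaden_training_set(
    data: TrainingSet,
    model: MultiStateModel,
    reference,
    seed: int = 0,
    fd_step: float = 5e-3,
    frequency_floor: float = 100.0,
) -> TrainingSet:
    """Wigner-broadening augmentation: one extra labeled point per record.

    At each record's geometry, an approximate Hessian is built by central
    finite differences of the *model's* ground-state forces; its normal
    modes (imaginary frequencies replaced by their magnitudes, then floored)
    seed one Wigner draw, which is labeled by the reference.  Output size is
    up to twice the input size; records whose Hessian fails are skipped.
    """
    rng = np.random.default_rng(seed)
    out = TrainingSet(list(data.records))
    for r_i, rec in enumerate(data):
        try:
            hess = _ml_hessian(model, rec.coords, rec.elements, fd_step)
            masses = np.asarray(masses_au(rec.elements))
            sqrt_m = np.sqrt(np.repeat(masses, 3))
            mw = hess / np.outer(sqrt_m, sqrt_m)
            w2, modes = np.linalg.eigh(0.5 * (mw + mw.T))
            freqs_cm1 = np.sqrt(np.abs(w2)) * HARTREE_IN_INVCM
            nm = NormalModeData(
                coords_ref=rec.coords, masses=masses, freqs_cm1=freqs_cm1,
                modes=modes, elements=list(rec.elements),
            )
            sample = wigner_sample(nm, 1, seed=int(rng.integers(2**31)),
                                   frequency_floor=frequency_floor)[0]
            res = reference.evaluate(sample.coords)
            out.append(
                TrainingRecord(
                    coords=sample.coords, elements=list(rec.elements),
                    energies=res.energies.copy(), forces=-res.gradients.copy(),
                    tag="broadening",
                )
            )
        except Exception as exc:
            logger.warning("broadening skipped record %d: %s", r_i, exc)
    return out


def _ml_hessian(model: MultiStateModel, coords, elements, h: float) -> np.ndarray:
    n3 = np.asarray(coords).size
    hess = np.zeros((n3, n3))
    flat = np.asarray(coords, dtype=float).ravel()
    for i in range(n3):
        xp = flat.copy(); xp[i] += h
        xm = flat.copy(); xm[i] -= h
        fp = model.predict_forces(xp.reshape(-1, 3), elements, [0])[0].ravel()
        fm = model.predict_forces(xm.reshape(-1, 3), elements, [0])[0].ravel()
        hess[:, i] = -(fp - fm) / (2.0 * h)
    return 0.5 * (hess + hess.T)


# -- initial data set -----------------------------------------------------


def build_initial_set(
    modes: NormalModeData,
    reference,
    batch: int = 50,
    stop_fraction: float = 0.10,
    seed: int = 0,
    max_batches: int = 20,
    cv_folds: int = 5,
    cv_schedule: Optional[TrainConfig] = None,
):
    """Wigner-sample the initial training set until learning saturates.

    Batches of ``batch`` Wigner samples are labeled by the reference.  After
    each batch the cross-validated MAE of a quick ground-state energy-only
    model is computed; a power-law learning curve fit projects the error at
    the next batch size, and sampling stops when the projected relative
    improvement falls below ``stop_fraction``.  Returns (training set,
    CV-error history).
    """
    cv_schedule = cv_schedule or TrainConfig(hidden=(32,), epochs=400,
                                             patience=400, val_fraction=0.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    data = TrainingSet([])
    history: List[float] = []
    for b in range(max_batches):
        samples = wigner_sample(modes, batch, seed=int(rng.integers(2**31)))
        for ic in samples:
            res = reference.evaluate(ic.coords)
            data.append(
                TrainingRecord(
                    coords=ic.coords, elements=list(modes.elements),
                    energies=res.energies.copy(),
                    forces=-res.gradients.copy(), tag="initial",
                )
            )
        history.append(
            _cv_error(data, cv_folds, int(rng.integers(2**31)), cv_schedule)
        )
        if len(history) >= 2:
            sizes = batch * np.arange(1, len(history) + 1)
            coef = np.polyfit(np.log(sizes), np.log(np.maximum(history, 1e-12)), 1)
            proj = float(np.exp(np.polyval(coef, np.log(sizes[-1] + batch))))
            improvement = (history[-1] - proj) / max(history[-1], 1e-300)
            if improvement < stop_fraction:
                break
    return data, history


def _cv_error(data: TrainingSet, folds: int, seed: int,
              schedule: TrainConfig) -> float:
    """k-fold CV MAE of a ground-state energy-only model."""
    rng = np.random.default_rng(seed)
    n = len(data)
    perm = rng.permutation(n)
    maes = []
    ground = TrainingSet(
        [
            TrainingRecord(r.coords, r.elements, r.energies[:1], None)
            for r in data
        ]
    )
    for f in range(folds):
        test_idx = perm[f::folds]
        train_idx = np.setdiff1d(perm, test_idx)
        model, _ = train(
            ground.subset(train_idx), "auxiliary",
            weights=LossWeights(1.0, 0.0, 0.0), seed=seed + f,
            schedule=schedule,
        )
        errs = [
            abs(
                float(model.predict_states(r.coords, r.elements, [0])[0])
                - float(r.energies[0])
            )
            for r in ground.subset(test_idx)
        ]
        maes.append(np.mean(errs))
    return float(np.mean(maes))


# -- the AL loop ----------------------------------------------------------


@dataclass
class ALConfig:
    n_states: int = 2
    n_tsh: int = 50
    initial_state: int = 1
    dt: float = 4.134                  # a.u. (~0.1 fs)
    max_time: float = 4134.0
    gap_threshold: float = 0.03
    with_gapmd: bool = True
    gapmd_max_time: Optional[float] = None   # defaults to max_time
    prob_tol: float = 0.10
    prob_cap: int = 15
    convergence_target: float = 0.95
    max_iterations: int = 25
    batch: int = 50
    stop_fraction: float = 0.10
    point_cap: Optional[int] = None
    broadening: bool = False
    excitation_window: Optional[Tuple[int, int, float, float]] = None
    train_schedule: TrainConfig = field(default_factory=TrainConfig)
    aux_hidden: Optional[Tuple[int, ...]] = None  # default: half the main width
    seed: int = 0


@dataclass
class ALState:
    iteration: int
    training_set: TrainingSet
    main_model: Optional[MultiStateModel]
    aux_model: Optional[MultiStateModel]
    thresholds: Optional[UQThresholds]
    history: List[dict] = field(default_factory=list)
    converged: bool = False
    seed_ledger: Dict[str, int] = field(default_factory=dict)

    @property
    def convergence_ratio(self) -> float:
        return self.history[-1]["convergence_ratio"] if self.history else 0.0


def _child_seed(base: int, *tags: int) -> int:
    return int(
        np.random.SeedSequence([base % (2**31), *tags]).generate_state(1)[0]
        % (2**31)
    )


def run_al(
    modes,
    reference,
    config: ALConfig,
    initial_set: Optional[TrainingSet] = None,
    thresholds: Optional[UQThresholds] = None,
) -> ALState:
    """Run the full active-learning loop.

    ``modes`` is one :class:`NormalModeData` or a list of them (trajectories
    are split evenly across starts).  ``reference`` labels geometries via
    ``evaluate``.  Returns the final :class:`ALState` with per-iteration
    history; ``converged`` is False (not an exception) when the iteration
    cap is reached first.
    """
    mode_sets = list(modes) if isinstance(modes, (list, tuple)) else [modes]
    elements = list(mode_sets[0].elements)
    cfg = config
    ledger: Dict[str, int] = {}

    def seed_for(name: str, *tags: int) -> int:
        # crc32 gives a stable (process-independent) name hash
        import zlib

        s = _child_seed(cfg.seed, zlib.crc32(name.encode()) % (2**20), *tags)
        ledger[f"{name}:{':'.join(map(str, tags))}"] = s
        return s

    if initial_set is None:
        data, cv_hist = build_initial_set(
            mode_sets[0], reference, batch=cfg.batch,
            stop_fraction=cfg.stop_fraction, seed=seed_for("initial"),
        )
    else:
        data, cv_hist = initial_set, []

    state = ALState(iteration=0, training_set=data, main_model=None,
                    aux_model=None, thresholds=thresholds,
                    seed_ledger=ledger)
    gapmd_time = cfg.gapmd_max_time or cfg.max_time

    for it in range(1, cfg.max_iterations + 1):
        train_data = data
        if cfg.broadening and state.main_model is not None:
            train_data = broaden_training_set(
                data, state.main_model, reference, seed=seed_for("broaden", it)
            )
        main, _ = train(train_data, "main", seed=seed_for("train_main", it),
                        schedule=cfg.train_schedule)
        # the auxiliary committee member is architecturally diversified: with
        # an identical layout, both models can agree far more tightly on the
        # initial validation set than any later retraining can reproduce,
        # which collapses the fixed UQ thresholds to an unreachable scale
        import dataclasses

        aux_hidden = cfg.aux_hidden or tuple(
            max(8, h // 2) for h in cfg.train_schedule.hidden
        )
        aux_schedule = dataclasses.replace(cfg.train_schedule,
                                           hidden=aux_hidden)
        aux, _ = train(train_data, "auxiliary", seed=seed_for("train_aux", it),
                       schedule=aux_schedule)
        state.main_model, state.aux_model = main, aux

        if thresholds is None:
            rng_val = np.random.default_rng(seed_for("valsplit"))
            n_init = len(data)
            n_val = max(1, int(round(0.1 * n_init)))
            idx = rng_val.permutation(n_init)[:n_val]
            thresholds = compute_thresholds(
                main, aux, [data[i].coords for i in idx], elements,
                n_states=cfg.n_states, validation_id=f"initial[{n_val}]",
            )
            state.thresholds = thresholds

        main_pot = main.as_potential(elements, cfg.n_states)
        monitor = ALMonitor(aux.as_potential(elements, cfg.n_states),
                            thresholds)

        # ML-TSH swarm (split across starting structures)
        trajs: List[Trajectory] = []
        for t_i in range(cfg.n_tsh):
            ms = mode_sets[t_i % len(mode_sets)]
            ic = wigner_sample(ms, 1, seed=seed_for("wigner", it, t_i))[0]
            if cfg.excitation_window is not None:
                fs, tos, ctr, hw = cfg.excitation_window
                kept = filter_excitation_window([ic], reference, fs, tos,
                                                ctr, hw)
                if not kept:
                    continue
                ic = kept[0]
            else:
                ic.state = cfg.initial_state
            trajs.append(
                propagate_tsh(ic, main_pot, dt=cfg.dt, max_time=cfg.max_time,
                              seed=seed_for("tsh", it, t_i),
                              al_monitor=monitor)
            )

        n_certain = sum(t.verdict == "completed" for t in trajs)
        ratio = n_certain / max(len(trajs), 1)
        iter_info = {
            "iteration": it,
            "n_train": len(data),
            "thresholds": thresholds.thresholds.copy(),
            "convergence_ratio": ratio,
            "verdicts": {
                v: sum(t.verdict == v for t in trajs)
                for v in set(t.verdict for t in trajs)
            },
        }

        if ratio >= cfg.convergence_target:
            iter_info["sampled"] = 0
            state.history.append(iter_info)
            state.iteration = it
            state.converged = True
            break

        # -- sample new points -------------------------------------------
        sampled: List[TrainingRecord] = []

        def add_point(coords, tag):
            res = reference.evaluate(coords)
            sampled.append(
                TrainingRecord(
                    coords=np.asarray(coords, dtype=float).copy(),
                    elements=list(elements), energies=res.energies.copy(),
                    forces=-res.gradients.copy(), tag=tag,
                )
            )

        for t in trajs:
            if t.verdict != "completed" and t.stop_step is not None:
                add_point(t.coords[t.stop_step], t.verdict)

        gap_trajs: List[Trajectory] = []
        if cfg.with_gapmd:
            spawns = spawn_gapmd(trajs, cfg.n_states,
                                 seed=seed_for("spawn", it))
            for g_i, (ic, pair, branch) in enumerate(spawns):
                gcfg = GapMDConfig(
                    threshold=cfg.gap_threshold, pair=pair, branch=branch,
                    dt=cfg.dt, max_time=gapmd_time,
                    seed=seed_for("gapmd", it, g_i),
                )
                gt = propagate_gapmd(ic, main_pot, gcfg, al_monitor=monitor)
                gap_trajs.append(gt)
                if gt.verdict != "completed" and gt.stop_step is not None:
                    add_point(gt.coords[gt.stop_step], f"gapmd-{gt.verdict}")

        for coords in probability_uncertain_points(
            trajs + gap_trajs, tol=cfg.prob_tol, cap=cfg.prob_cap,
            seed=seed_for("prob", it),
        ):
            add_point(coords, "probability")

        if cfg.point_cap is not None:
            sampled = sampled[: cfg.point_cap]

        data.extend(sampled)
        iter_info["sampled"] = len(sampled)
        iter_info["sampled_by_tag"] = {
            tag: sum(r.tag == tag for r in sampled)
            for tag in set(r.tag for r in sampled)
        }
        state.history.append(iter_info)
        state.iteration = it
        if not sampled:
            logger.warning("iteration %d sampled no points; stopping", it)
            break

    state.training_set = data
    return state
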