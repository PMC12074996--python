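"""Multi-state machine-learned potentials.

The central architecture treats the electronic state ordering number as an
input feature: every atomic descriptor vector is extended by one component,
``state_index * state_scale``, and a single set of per-element networks maps
(descriptor + state feature) to an atomic energy contribution.  Atomic
contributions plus per-element self-atomic energies sum to the total energy
of the requested adiabatic state.  Because the state enters as a feature,
one model covers any number of states, and records with different state
counts can be mixed in one training set.

Training minimizes

    L = w_E * L_E + w_F * L_F + w_gap * L_gap

where ``L_gap`` is the mean squared error of adjacent-state energy gaps —
the term that keeps near-degeneracy regions (where surface hops happen)
accurate.  ``L_E``/``L_F``/``L_gap`` are means over all labeled scalar
entries, so the weights stay comparable across dataset sizes.

Two baseline architectures are provided for comparison: ``single_state``
(one independent network set per state) and ``multi_output`` (one network
set with as many outputs as states).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._mlp import MLP, Adam
from .descriptors import DescriptorConfig, DisplacementConfig, featurize
from .training_data import TrainingRecord, TrainingSet

logger = logging.getLogger(__name__)

__all__ = [
    "LossWeights",
    "LossValue",
    "MultiStateModel",
    "MLPotential",
    "TrainConfig",
    "TrainingError",
    "compute_loss",
    "predict_states",
    "predict_forces",
    "train",
    "featurize",
]

#: fixed scaling of the integer state index before it joins the descriptor
STATE_FEATURE_SCALE = 1.0 / 8.0


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite loss; defaults w_E = w_gap = 1, w_F = 0.1."""

    energy: float = 1.0
    force: float = 0.1
    gap: float = 1.0

    def __post_init__(self):
        if min(self.energy, self.force, self.gap) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class LossValue:
    total: float
    energy: float
    force: float
    gap: float


@dataclass
class TrainConfig:
    """Optimization schedule for :func:`train`."""

    hidden: Tuple[int, ...] = (64, 64)
    lr: float = 1e-2
    lr_final_factor: float = 0.02  # cosine decay down to lr * factor
    epochs: int = 3000
    patience: int = 400        # early stopping on validation loss
    val_fraction: float = 0.10
    descriptor: object = None  # DescriptorConfig / DisplacementConfig; auto if None
    verbose: bool = False

    def lr_at(self, epoch: int) -> float:
        lo = self.lr * self.lr_final_factor
        frac = 0.5 * (1.0 + np.cos(np.pi * epoch / max(self.epochs - 1, 1)))
        return lo + (self.lr - lo) * frac


@dataclass
class MultiStateModel:
    """Trained potential mapping (geometry, state index) -> energy."""

    descriptor: object
    networks: Dict[str, MLP]
    sae: Dict[str, float]
    n_states_trained: int
    arch: str = "multi_state"         # multi_state | multi_output | single_state
    flavor: str = "main"              # main | auxiliary | baseline
    state_scale: float = STATE_FEATURE_SCALE
    seed: int = 0
    single_state_index: Optional[int] = None

    _warned_extrapolation: bool = field(default=False, repr=False, compare=False)

    # -- prediction -------------------------------------------------------

    def _sae_total(self, elements) -> float:
        return float(sum(self.sae.get(e, 0.0) for e in elements))

    def _check_states(self, states) -> List[int]:
        states = [int(s) for s in states]
        if any(s < 0 for s in states):
            raise ValueError("state indices must be non-negative")
        if self.arch == "multi_output":
            bad = [s for s in states if s >= self.n_states_trained]
            if bad:
                raise ValueError(
                    f"multi_output model has {self.n_states_trained} outputs; "
                    f"cannot predict state {bad[0]}"
                )
        elif any(s >= self.n_states_trained for s in states):
            if not self._warned_extrapolation:
                logger.warning(
                    "state index beyond trained maximum %d: extrapolating",
                    self.n_states_trained - 1,
                )
                object.__setattr__(self, "_warned_extrapolation", True)
        return states

    def predict_states(self, coords, elements, states) -> np.ndarray:
        states = self._check_states(states)
        desc = self.descriptor.featurize(coords, elements)
        site_elems = self.descriptor.site_elements(elements)
        base = self._sae_total(elements)
        energies = np.full(len(states), base)
        if self.arch == "multi_output":
            for i, e in enumerate(site_elems):
                out = self.networks[e](desc[i : i + 1])[0]
                for k, s in enumerate(states):
                    energies[k] += out[s]
        elif self.arch == "single_state":
            for i, e in enumerate(site_elems):
                val = float(self.networks[e](desc[i : i + 1])[0, 0])
                energies += val
        else:
            n_s = len(states)
            svals = np.repeat(np.array(states, dtype=float) * self.state_scale,
                              desc.shape[0])
            feat = np.hstack(
                [np.tile(desc, (n_s, 1)), svals[:, None]]
            )  # rows ordered (state, site)
            by_elem: Dict[str, list] = {}
            for i, e in enumerate(site_elems):
                by_elem.setdefault(e, []).append(i)
            n_sites = desc.shape[0]
            for e, idx in by_elem.items():
                rows = np.concatenate(
                    [np.asarray(idx) + k * n_sites for k in range(n_s)]
                )
                out = self.networks[e](feat[rows])[:, 0]
                energies += out.reshape(n_s, len(idx)).sum(axis=1)
        return energies

    def predict_forces(self, coords, elements, states) -> np.ndarray:
        return self.energies_and_forces(coords, elements, states)[1]

    def energies_and_forces(self, coords, elements, states):
        """Shared-featurization evaluation of energies and forces.

        Forces are exact negative gradients of the predicted energies,
        obtained by differentiating the network and chaining through the
        descriptor Jacobian.
        """
        states = self._check_states(states)
        desc, jac = self.descriptor.featurize_with_jacobian(coords, elements)
        site_elems = self.descriptor.site_elements(elements)
        n_atoms = np.asarray(coords).shape[0]
        energies = np.full(len(states), self._sae_total(elements))
        grads = np.zeros((len(states), n_atoms, 3))
        if self.arch == "multi_output":
            for i, e in enumerate(site_elems):
                out, acts = self.networks[e].forward(desc[i : i + 1])
                for k, s in enumerate(states):
                    energies[k] += out[0, s]
                    g_in = self.networks[e].input_grad(acts, out_index=s)[0]
                    grads[k] += np.einsum("d,dna->na", g_in, jac[i])
        elif self.arch == "single_state":
            for i, e in enumerate(site_elems):
                out, acts = self.networks[e].forward(desc[i : i + 1])
                g_in = self.networks[e].input_grad(acts)[0]
                contrib = np.einsum("d,dna->na", g_in, jac[i])
                energies += out[0, 0]
                grads += contrib[None]
        else:
            n_s = len(states)
            n_sites = desc.shape[0]
            svals = np.repeat(np.array(states, dtype=float) * self.state_scale,
                              n_sites)
            feat = np.hstack([np.tile(desc, (n_s, 1)), svals[:, None]])
            by_elem: Dict[str, list] = {}
            for i, e in enumerate(site_elems):
                by_elem.setdefault(e, []).append(i)
            for e, idx in by_elem.items():
                idx = np.asarray(idx)
                rows = np.concatenate(
                    [idx + k * n_sites for k in range(n_s)]
                )
                net = self.networks[e]
                out, acts = net.forward(feat[rows])
                energies += out[:, 0].reshape(n_s, len(idx)).sum(axis=1)
                g_in = net.input_grad(acts)[:, :-1]  # (n_s*len(idx), D)
                g_in = g_in.reshape(n_s, len(idx), -1)
                grads += np.einsum("ksd,sdna->kna", g_in, jac[idx])
        return energies, -grads

    def as_potential(self, elements, n_states: Optional[int] = None) -> "MLPotential":
        return MLPotential(self, list(elements), n_states or self.n_states_trained)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        import json

        arrays = {}
        meta = {
            "arch": self.arch,
            "flavor": self.flavor,
            "n_states_trained": self.n_states_trained,
            "state_scale": self.state_scale,
            "seed": self.seed,
            "single_state_index": self.single_state_index,
            "sae": self.sae,
            "elements": sorted(self.networks),
            "dims": {e: list(self.networks[e].dims) for e in self.networks},
        }
        if isinstance(self.descriptor, DisplacementConfig):
            meta["descriptor"] = {"kind": "displacement",
                                  "scale": self.descriptor.scale}
            arrays["desc_ref_coords"] = self.descriptor.ref_coords
        else:
            d = self.descriptor
            meta["descriptor"] = {
                "kind": "symmetry_functions",
                "elements": list(d.elements),
                "radial_cutoff": d.radial_cutoff,
                "angular_cutoff": d.angular_cutoff,
                "radial_centers": list(d.radial_centers),
                "radial_eta": d.radial_eta,
                "angular_centers": list(d.angular_centers),
                "angular_eta": d.angular_eta,
                "theta_centers": list(d.theta_centers),
                "zeta": d.zeta,
            }
        for e, net in self.networks.items():
            for li, (w, b) in enumerate(zip(net.weights, net.biases)):
                arrays[f"w_{e}_{li}"] = w
                arrays[f"b_{e}_{li}"] = b
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MultiStateModel":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            dk = meta["descriptor"]
            if dk["kind"] == "displacement":
                descriptor = DisplacementConfig(
                    ref_coords=data["desc_ref_coords"], scale=dk["scale"]
                )
            else:
                descriptor = DescriptorConfig(
                    elements=tuple(dk["elements"]),
                    radial_cutoff=dk["radial_cutoff"],
                    angular_cutoff=dk["angular_cutoff"],
                    radial_centers=tuple(dk["radial_centers"]),
                    radial_eta=dk["radial_eta"],
                    angular_centers=tuple(dk["angular_centers"]),
                    angular_eta=dk["angular_eta"],
                    theta_centers=tuple(dk["theta_centers"]),
                    zeta=dk["zeta"],
                )
            networks = {}
            for e in meta["elements"]:
                net = MLP.__new__(MLP)
                net.dims = tuple(meta["dims"][e])
                net.weights = []
                net.biases = []
                li = 0
                while f"w_{e}_{li}" in data:
                    net.weights.append(data[f"w_{e}_{li}"].copy())
                    net.biases.append(data[f"b_{e}_{li}"].copy())
                    li += 1
                networks[e] = net
        return cls(
            descriptor=descriptor,
            networks=networks,
            sae=dict(meta["sae"]),
            n_states_trained=meta["n_states_trained"],
            arch=meta["arch"],
            flavor=meta["flavor"],
            state_scale=meta["state_scale"],
            seed=meta["seed"],
            single_state_index=meta["single_state_index"],
        )


class MLPotential:
    """Adapter presenting a :class:`MultiStateModel` as a dynamics potential.

    Unlike the analytic oracle, the ML energies are indexed by state number
    and are *not* guaranteed ascending: a negative predicted gap is exactly
    what the active-learning negative-gap check is there to catch.
    """

    def __init__(self, model: MultiStateModel, elements, n_states: int):
        self.model = model
        self.elements = list(elements)
        self.n_states = int(n_states)

    def evaluate(self, coords):
        from .model_surfaces import AdiabaticResult

        states = list(range(self.n_states))
        energies, forces = self.model.energies_and_forces(
            coords, self.elements, states
        )
        return AdiabaticResult(
            energies=energies, gradients=-forces, gaps=np.diff(energies)
        )

    def energies(self, coords) -> np.ndarray:
        return self.model.predict_states(
            coords, self.elements, list(range(self.n_states))
        )


# -- public functional ops ------------------------------------------------


def predict_states(model: MultiStateModel, coords, elements, states):
    return model.predict_states(coords, elements, states)


def predict_forces(model: MultiStateModel, coords, elements, states):
    return model.predict_forces(coords, elements, states)


def compute_loss(e_ml, f_ml, e_ref, f_ref, weights: LossWeights) -> LossValue:
    """Composite loss from per-record energy/force arrays.

    ``e_ml``/``e_ref``: sequences of per-record per-state energy arrays;
    ``f_ml``/``f_ref``: matching per-record (n_states, n_atoms, 3) force
    arrays, or None for energy-only data.  Each component is a mean over all
    labeled scalar entries; gaps are taken between adjacent states within
    each record.
    """
    e_sq, gap_sq, f_sq = [], [], []
    n_rec = len(e_ref)
    for r in range(n_rec):
        ml = np.asarray(e_ml[r], dtype=float)
        ref = np.asarray(e_ref[r], dtype=float)
        if ml.shape != ref.shape:
            raise ValueError(
                f"record {r}: predicted {ml.shape} vs reference {ref.shape} "
                "state counts differ"
            )
        e_sq.append((ml - ref) ** 2)
        if len(ref) >= 2:
            gap_sq.append((np.diff(ml) - np.diff(ref)) ** 2)
        if f_ml is not None and f_ref is not None and f_ref[r] is not None:
            fm = np.asarray(f_ml[r], dtype=float)
            fr = np.asarray(f_ref[r], dtype=float)
            if fm.shape != fr.shape:
                raise ValueError(f"record {r}: force shapes differ")
            f_sq.append(((fm - fr) ** 2).ravel())
    l_e = float(np.mean(np.concatenate(e_sq))) if e_sq else 0.0
    l_gap = float(np.mean(np.concatenate(gap_sq))) if gap_sq else 0.0
    l_f = float(np.mean(np.concatenate(f_sq))) if f_sq else 0.0
    total = weights.energy * l_e + weights.force * l_f + weights.gap * l_gap
    return LossValue(total=total, energy=l_e, force=l_f, gap=l_gap)


def fit_self_atomic_energies(data: TrainingSet) -> Dict[str, float]:
    """Least-squares fit of per-element counts to ground-state energies."""
    elems = sorted({e for r in data for e in r.elements})
    counts = np.array(
        [[r.elements.count(e) for e in elems] for r in data], dtype=float
    )
    y = np.array([r.energies[0] for r in data])
    coef, *_ = np.linalg.lstsq(counts, y, rcond=None)
    return {e: float(c) for e, c in zip(elems, coef)}


def default_descriptor(data: TrainingSet):
    """Displacement descriptor when all records share one skeleton, else
    symmetry functions over the elements present."""
    shapes = {(r.coords.shape[0], tuple(r.elements)) for r in data}
    if len(shapes) == 1:
        return DisplacementConfig(ref_coords=data[0].coords.copy())
    elems = tuple(sorted({e for r in data for e in r.elements}))
    return DescriptorConfig(elements=elems)


def train(
    data: TrainingSet,
    arch: str = "main",
    weights: Optional[LossWeights] = None,
    seed: int = 0,
    schedule: Optional[TrainConfig] = None,
):
    """Train a potential of the requested architecture.

    ``arch``: ``main`` (multi-state, energies+forces+gaps), ``auxiliary``
    (multi-state, energies+gaps only), ``single_state`` (list of per-state
    models) or ``multi_output``.  Returns ``(model_or_models, history)``;
    history holds per-epoch training and validation losses.
    """
    if len(data) == 0:
        raise ValueError("training set is empty")
    if arch not in ("main", "auxiliary", "single_state", "multi_output"):
        raise ValueError(f"unknown architecture {arch!r}")
    weights = weights or LossWeights()
    schedule = schedule or TrainConfig()

    if arch == "main":
        if any(r.forces is None for r in data):
            raise ValueError("main flavor requires forces on every record")
    if arch == "auxiliary":
        weights = LossWeights(weights.energy, 0.0, weights.gap)
    if arch == "multi_output" and weights.force > 0 and any(
        r.forces is not None for r in data
    ):
        logger.info("multi_output baseline trains on energies/gaps only; "
                    "force weight ignored")
        weights = LossWeights(weights.energy, 0.0, weights.gap)

    if arch == "single_state":
        n_states = data.max_states
        models, histories = [], []
        for s in range(n_states):
            sub = TrainingSet([r for r in data if r.n_states > s])
            sub_s = TrainingSet(
                [
                    TrainingRecord(
                        r.coords,
                        r.elements,
                        np.array([r.energies[s]]),
                        None if r.forces is None else r.forces[s : s + 1],
                    )
                    for r in sub
                ]
            )
            w_s = LossWeights(weights.energy, weights.force, 0.0)
            model, hist = _train_one(
                sub_s, "single_state", w_s, seed + s, schedule
            )
            model.single_state_index = s
            models.append(model)
            histories.append(hist)
        return models, histories

    return _train_one(data, arch, weights, seed, schedule)


def _train_one(data: TrainingSet, arch: str, weights: LossWeights,
               seed: int, schedule: TrainConfig):
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 912]))

    n = len(data)
    n_val = int(round(schedule.val_fraction * n)) if n >= 5 else 0
    perm = rng.permutation(n)
    val_idx = sorted(perm[:n_val].tolist())
    train_idx = sorted(perm[n_val:].tolist())
    train_set = data.subset(train_idx)
    val_set = data.subset(val_idx)

    sae = fit_self_atomic_energies(data)
    descriptor = schedule.descriptor or default_descriptor(data)
    s_max = data.max_states
    multi_state = arch in ("main", "auxiliary")
    n_out = s_max if arch == "multi_output" else 1
    use_forces = weights.force > 0 and all(r.forces is not None for r in train_set)

    d_dim = descriptor.dim + (1 if multi_state else 0)
    elem_order = sorted(
        set().union(*(descriptor.site_elements(r.elements) for r in data))
    )
    networks = {
        e: MLP((d_dim, *schedule.hidden, n_out), rng) for e in elem_order
    }

    batch = _Batch(train_set, descriptor, sae, multi_state, use_forces,
                   STATE_FEATURE_SCALE)
    val_batch = (
        _Batch(val_set, descriptor, sae, multi_state, False,
               STATE_FEATURE_SCALE)
        if len(val_set)
        else None
    )

    opts = {e: Adam(networks[e].parameters(), lr=schedule.lr)
            for e in elem_order}

    history = {"train": [], "val": []}
    best_val = np.inf
    best_weights = None
    best_epoch = 0
    for epoch in range(schedule.epochs):
        lr_now = schedule.lr_at(epoch)
        for opt in opts.values():
            opt.lr = lr_now
        loss = batch.step(networks, opts, weights)
        if not np.isfinite(loss.total):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        history["train"].append(loss)
        if val_batch is not None:
            vloss = val_batch.eval_loss(networks, weights)
            history["val"].append(vloss)
            if vloss.total < best_val - 1e-14:
                best_val = vloss.total
                best_epoch = epoch
                best_weights = {
                    e: ( [w.copy() for w in networks[e].weights],
                         [b.copy() for b in networks[e].biases] )
                    for e in elem_order
                }
            elif epoch - best_epoch > schedule.patience:
                break
        if schedule.verbose and epoch % 200 == 0:
            logger.info("epoch %d train %.3e", epoch, loss.total)
    if best_weights is not None:
        for e in elem_order:
            networks[e].weights = best_weights[e][0]
            networks[e].biases = best_weights[e][1]

    flavor = {"main": "main", "auxiliary": "auxiliary"}.get(arch, "baseline")
    model = MultiStateModel(
        descriptor=descriptor,
        networks=networks,
        sae=sae,
        n_states_trained=s_max,
        arch="multi_state" if multi_state else arch,
        flavor=flavor,
        seed=seed,
    )
    return model, history


class _Batch:
    """Precomputed row tables for full-batch training on a record set."""

    def __init__(self, records: TrainingSet, descriptor, sae, multi_state,
                 use_forces, state_scale):
        self.multi_state = multi_state
        self.use_forces = use_forces
        n_rec = len(records)
        s_max = max((r.n_states for r in records), default=1)
        self.n_rec, self.s_max = n_rec, s_max

        self.e_ref = np.zeros((n_rec, s_max))
        self.mask = np.zeros((n_rec, s_max), dtype=bool)
        self.sae_base = np.zeros(n_rec)
        self.n3 = np.zeros(n_rec, dtype=int)
        for r_i, rec in enumerate(records):
            ns = rec.n_states if multi_state or s_max > 1 else 1
            self.e_ref[r_i, : rec.n_states] = rec.energies
            self.mask[r_i, : rec.n_states] = True
            self.sae_base[r_i] = sum(sae.get(e, 0.0) for e in rec.elements)
            self.n3[r_i] = rec.coords.size
        self.count_e = int(self.mask.sum())
        self.gap_mask = self.mask[:, 1:] & self.mask[:, :-1]
        self.count_gap = int(self.gap_mask.sum())
        self.gap_ref = np.where(
            self.gap_mask, np.diff(self.e_ref, axis=1), 0.0
        )

        n3_max = max(int(r.coords.size) for r in records)
        self.n3_max = n3_max
        if use_forces:
            self.f_ref = np.zeros((n_rec, s_max, n3_max))
            self.f_mask = np.zeros((n_rec, s_max, n3_max), dtype=bool)
            self.count_f = 0
            for r_i, rec in enumerate(records):
                fr = rec.forces.reshape(rec.n_states, -1)
                self.f_ref[r_i, : rec.n_states, : fr.shape[1]] = fr
                self.f_mask[r_i, : rec.n_states, : fr.shape[1]] = True
                self.count_f += fr.size

        # per-element row tables
        self.rows = {}
        tmp = {}
        for r_i, rec in enumerate(records):
            desc, jac = (
                descriptor.featurize_with_jacobian(rec.coords, rec.elements)
                if use_forces
                else (descriptor.featurize(rec.coords, rec.elements), None)
            )
            site_elems = descriptor.site_elements(rec.elements)
            state_range = range(rec.n_states) if multi_state else [0]
            for site, elem in enumerate(site_elems):
                for s in state_range:
                    row_x = (
                        np.hstack([desc[site], [s * state_scale]])
                        if multi_state
                        else desc[site]
                    )
                    entry = tmp.setdefault(elem, {"x": [], "rec": [], "st": [],
                                                  "jac": []})
                    entry["x"].append(row_x)
                    entry["rec"].append(r_i)
                    entry["st"].append(s)
                    if use_forces:
                        j = np.zeros((descriptor.dim, n3_max))
                        j[:, : rec.coords.size] = jac[site].reshape(
                            descriptor.dim, -1
                        )
                        entry["jac"].append(j)
        for elem, entry in tmp.items():
            self.rows[elem] = {
                "x": np.array(entry["x"]),
                "rec": np.array(entry["rec"]),
                "st": np.array(entry["st"]),
                "jac": np.array(entry["jac"]) if use_forces else None,
            }

    # -- evaluation helpers ----------------------------------------------

    def _energies(self, networks, want_cache=False):
        e_ml = np.tile(self.sae_base[:, None], (1, self.s_max))
        caches = {}
        for elem, rows in self.rows.items():
            out, acts = networks[elem].forward(rows["x"])
            if out.shape[1] == 1:
                np.add.at(e_ml, (rows["rec"], rows["st"]), out[:, 0])
            else:  # multi_output: scatter every output column
                np.add.at(e_ml, rows["rec"], out)
            if want_cache:
                caches[elem] = acts
        return e_ml, caches

    def eval_loss(self, networks, weights: LossWeights) -> LossValue:
        e_ml, _ = self._energies(networks)
        l_e, l_gap, _, _ = self._energy_residuals(e_ml)
        total = weights.energy * l_e + weights.gap * l_gap
        return LossValue(total=total, energy=l_e, force=0.0, gap=l_gap)

    def _energy_residuals(self, e_ml):
        res = np.where(self.mask, e_ml - self.e_ref, 0.0)
        l_e = float((res**2).sum() / self.count_e)
        gap_res = np.where(
            self.gap_mask, np.diff(e_ml, axis=1) - self.gap_ref, 0.0
        )
        l_gap = (
            float((gap_res**2).sum() / self.count_gap) if self.count_gap else 0.0
        )
        return l_e, l_gap, res, gap_res

    def step(self, networks, opts, weights: LossWeights) -> LossValue:
        e_ml, caches = self._energies(networks, want_cache=True)
        l_e, l_gap, res, gap_res = self._energy_residuals(e_ml)

        # seed on each (record, state) energy
        d_e = (2.0 * weights.energy / self.count_e) * res
        if self.count_gap and weights.gap > 0:
            g = (2.0 * weights.gap / self.count_gap) * gap_res
            d_e[:, 1:] += g
            d_e[:, :-1] -= g

        l_f = 0.0
        g_rows_by_elem = {}
        if self.use_forces:
            f_ml = np.zeros((self.n_rec, self.s_max, self.n3_max))
            for elem, rows in self.rows.items():
                g_rows = networks[elem].input_grad(caches[elem])
                g_desc = g_rows[:, : rows["jac"].shape[1]]
                g_rows_by_elem[elem] = g_rows
                contrib = -np.einsum("bd,bdk->bk", g_desc, rows["jac"])
                np.add.at(f_ml, (rows["rec"], rows["st"]), contrib)
            f_err = np.where(self.f_mask, f_ml - self.f_ref, 0.0)
            l_f = float((f_err**2).sum() / self.count_f)

        for elem, rows in self.rows.items():
            net = networks[elem]
            if net.n_out == 1:
                d_out = d_e[rows["rec"], rows["st"]][:, None]
            else:
                d_out = d_e[rows["rec"], :]
            if self.use_forces and weights.force > 0:
                err_rows = f_err[rows["rec"], rows["st"]]
                c = -(2.0 * weights.force / self.count_f) * np.einsum(
                    "bk,bdk->bd", err_rows, rows["jac"]
                )
                if self.multi_state:
                    c = np.hstack([c, np.zeros((c.shape[0], 1))])
                s_out, t_cache = net.tangent(caches[elem], c)
                d_s = np.ones_like(s_out)
                gw, gb = net.backward(caches[elem], d_out, t_cache, d_s)
            else:
                gw, gb = net.backward(caches[elem], d_out)
            opts[elem].step(gw + gb)

        total = (
            weights.energy * l_e + weights.force * l_f + weights.gap * l_gap
        )
        return LossValue(total=total, energy=l_e, force=l_f, gap=l_gap)
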