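"""Rate-coded network state and the 200-cycle settling loop.

Units carry activity rates in [0, 1].  Each cycle, every layer's net input is
computed synchronously from the previous cycle's activities, layer inhibition
is set by tie-tolerant kWTA (optionally modulated by the sinusoidal
oscillation during training), and activities move a step ``dt`` toward the
S-shaped activation target.  A trial is 200 such cycles; training trials end
with the U-shaped weight update, test trials are side-effect-free.

The whole state is batched over independent model runs: activity arrays have
shape (batch, n_units) and weight matrices (batch, n_send, n_recv), so 50
runs settle in lockstep through one set of vectorised operations.
"""

from __future__ import annotations

import numpy as np

from . import params as P
from .inhibition import inhibition_thresholds, kwta_inhibition, oscillate_inhibition
from .params import LayerParams, ProjectionParams, TRIAL_CYCLES
from .plasticity import RunningAverages, apply_weight_update, coactivity


def activation_function(net_input, inhibition, gain: float, threshold: float):
    """S-shaped, bounded rate: ``g(x) = gain*x / (gain*x + 1)`` on the
    above-threshold drive ``x = net - threshold - inhibition`` (0 below).

    Monotone in the drive, zero at or below threshold, asymptotically
    approaches (never reaches) 1; higher gain is steeper.
    """
    drive = np.maximum(np.asarray(net_input, dtype=float) - threshold - inhibition, 0.0)
    gx = gain * drive
    return gx / (gx + 1.0)


class Layer:
    """One layer: parameters plus batched per-cycle state."""

    def __init__(self, spec: LayerParams, batch: int) -> None:
        self.spec = spec
        self.batch = batch
        self.act = np.zeros((batch, spec.n_units))
        self.net = np.zeros((batch, spec.n_units))
        self.gi = np.zeros(batch)
        self.external = None  # (batch, n_units) clamp pattern or None
        self.traces = RunningAverages(batch, spec.n_units)

    def reset(self) -> None:
        self.act[...] = 0.0
        self.net[...] = 0.0
        self.gi[...] = 0.0
        self.external = None
        self.traces.reset(0.0)


class Projection:
    """Bidirectional projection: one weight matrix, two directional scales."""

    def __init__(self, spec: ProjectionParams, sender: Layer, receiver: Layer,
                 weights: np.ndarray) -> None:
        if spec.sender != sender.spec.name or spec.receiver != receiver.spec.name:
            raise ValueError("projection spec does not match the given layers")
        expected = (sender.batch, sender.spec.n_units, receiver.spec.n_units)
        if weights.shape != expected:
            raise ValueError(f"weight matrix shape {weights.shape} does not "
                             f"match layers (expected {expected})")
        self.spec = spec
        self.sender = sender
        self.receiver = receiver
        self.recurrent = sender is receiver
        self.weights = weights
        if self.recurrent:
            n = sender.spec.n_units
            self.weights[:, np.arange(n), np.arange(n)] = 0.0

    def prewire(self, sender_idx, receiver_idx, strength: float = P.PREWIRE_STRENGTH,
                runs=slice(None)) -> None:
        """Overwrite the block (sender_idx x receiver_idx) with ``strength``."""
        si = np.atleast_1d(np.asarray(sender_idx))
        ri = np.atleast_1d(np.asarray(receiver_idx))
        self.weights[np.ix_(np.atleast_1d(np.arange(self.weights.shape[0])[runs]),
                            si, ri)] = strength
        if self.recurrent:
            n = self.weights.shape[-1]
            self.weights[:, np.arange(n), np.arange(n)] = 0.0


class Network:
    """Layers, projections and the settling/trial loop for a batch of runs."""

    def __init__(self, layers: dict[str, LayerParams],
                 projections: list[ProjectionParams],
                 batch: int, seed=None,
                 dt: float = P.DEFAULT_DT,
                 norm_exponent: float = P.NET_NORM_EXPONENT) -> None:
        self.batch = batch
        self.dt = dt
        self.norm_exponent = norm_exponent
        self.cycle = 0
        self.layers: dict[str, Layer] = {name: Layer(sp, batch)
                                         for name, sp in layers.items()}
        # One RNG stream per run so each run's weights depend only on its seed.
        if not isinstance(seed, np.random.SeedSequence):
            seed = np.random.SeedSequence(seed)
        seqs = seed.spawn(batch)
        run_rngs = [np.random.default_rng(s) for s in seqs]
        self.projections: list[Projection] = []
        for pspec in projections:
            if pspec.sender not in self.layers or pspec.receiver not in self.layers:
                raise ValueError(
                    f"projection {pspec.sender}->{pspec.receiver} references "
                    "a layer that does not exist")
            sender = self.layers[pspec.sender]
            receiver = self.layers[pspec.receiver]
            lo, hi = pspec.wt_range
            shape = (sender.spec.n_units, receiver.spec.n_units)
            weights = np.stack([rng.uniform(lo, hi, size=shape)
                                for rng in run_rngs])
            self.projections.append(Projection(pspec, sender, receiver, weights))
        # Incoming projection lists per layer: (projection, forward?) pairs.
        self._incoming: dict[str, list[tuple[Projection, bool]]] = {
            name: [] for name in self.layers
        }
        for proj in self.projections:
            self._incoming[proj.receiver.spec.name].append((proj, True))
            if not proj.recurrent:
                self._incoming[proj.sender.spec.name].append((proj, False))

    # -- configuration helpers -------------------------------------------------

    def projection(self, sender: str, receiver: str) -> Projection:
        for proj in self.projections:
            if proj.spec.sender == sender and proj.spec.receiver == receiver:
                return proj
        raise KeyError(f"no projection {sender}->{receiver}")

    # -- dynamics --------------------------------------------------------------

    def compute_net_input(self, name: str) -> np.ndarray:
        """Net excitatory input to one layer from all incoming projections.

        Each projection contributes ``wt_scale_dir * sum_j(w_ij * a_j) / d_s``
        where the divisor ``d_s = k_s**lam * N_s**(1-lam)`` interpolates
        between the sending layer's expected active count (its kWTA k) and its
        size, so Table-2 style scales are layer-size independent.  An external
        clamp adds ``clamp_gain * external``.
        """
        layer = self.layers[name]
        net = np.zeros_like(layer.net)
        lam = self.norm_exponent
        for proj, forward in self._incoming[name]:
            if forward:
                src = proj.sender
                scale = proj.spec.scale_fwd
                w = proj.weights
                summed = np.matmul(src.act[:, None, :], w)[:, 0, :]
            else:
                src = proj.receiver
                scale = proj.spec.scale_bwd
                summed = np.matmul(proj.weights, src.act[:, :, None])[:, :, 0]
            if src.spec.norm_count is not None:
                divisor = src.spec.norm_count
            else:
                divisor = src.spec.k ** lam * src.spec.n_units ** (1.0 - lam)
            net += (scale / divisor) * summed
        if layer.external is not None and layer.spec.clamp_gain > 0:
            net += layer.spec.clamp_gain * layer.external
        return net

    def settle_cycle(self, train: bool = False) -> None:
        """One synchronous update of every layer; increments the cycle count."""
        self.cycle += 1
        nets = {name: self.compute_net_input(name) for name in self.layers}
        for name, layer in self.layers.items():
            sp = layer.spec
            layer.net = nets[name]
            g_ranked = inhibition_thresholds(layer.net, sp.threshold)
            gi = kwta_inhibition(g_ranked, sp.k, sp.k_max, sp.kwta_point,
                                 sp.target_diff)
            if train:
                gi = oscillate_inhibition(gi, sp.osc, self.cycle)
            layer.gi = np.asarray(gi)
            target = activation_function(layer.net, layer.gi[:, None],
                                         sp.gain, sp.threshold)
            dt = sp.dt if sp.dt is not None else self.dt
            layer.act += dt * (target - layer.act)
            layer.traces.update(layer.act)

    def reset_trial(self) -> None:
        self.cycle = 0
        for layer in self.layers.values():
            layer.reset()

    def set_stimulus(self, stimulus: dict[str, np.ndarray]) -> None:
        """Clamp one-hot external patterns onto the input layers.

        ``stimulus`` maps layer name -> (batch, n_units) pattern; every input
        layer pattern must have exactly one active unit per run.
        """
        for name, pattern in stimulus.items():
            pattern = np.asarray(pattern, dtype=float)
            layer = self.layers[name]
            if pattern.shape != layer.act.shape:
                raise ValueError(f"stimulus for layer {name} has shape "
                                 f"{pattern.shape}, expected {layer.act.shape}")
            if not np.all(np.sum(pattern > 0, axis=1) == 1):
                raise ValueError(f"stimulus for input layer {name} must "
                                 "activate exactly one unit per run")
            layer.external = pattern

    def run_trial(self, stimulus: dict[str, np.ndarray], train: bool):
        """Run one 200-cycle trial; learn at the end if ``train``.

        Returns a dict of final-cycle activity snapshots per layer
        (copies, shape (batch, n_units)).
        """
        self.reset_trial()
        self.set_stimulus(stimulus)
        for _ in range(TRIAL_CYCLES):
            self.settle_cycle(train=train)
        if train:
            self.apply_learning()
        return {name: layer.act.copy() for name, layer in self.layers.items()}

    def apply_learning(self) -> None:
        """End-of-trial U-shaped weight update on all learnable projections."""
        for proj in self.projections:
            if not proj.spec.learnable:
                continue
            kappa = coactivity(proj.receiver.traces.medium,
                               proj.sender.traces.medium)
            apply_weight_update(proj.weights, kappa, proj.spec.ushape,
                                exclude_diagonal=proj.recurrent)
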