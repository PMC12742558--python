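"""Sine-activated coordinate network (Siren) with hand-written gradients.

The network maps a normalized coordinate (3 spatial components, plus one time
component rescaled to [-1, 1] when ``time_dependent``) to a 3-vector. Hidden
layers apply ``sin(omega0 * (W z + b))``; the output layer is linear and the
raw output is multiplied elementwise by ``output_scale`` (voxel units).

With the sinusoidal initialization used here (first layer uniform in
+/- 1/in_dim, deeper layers uniform in +/- sqrt(6/fan_in)/omega0) the scaled
output magnitude at initialization stays well within two voxel units, which
keeps the initial map close to the identity.

Gradients — with respect to parameters and with respect to the inputs — are
computed by explicit reverse-mode passes over a stored forward tape; no
autodiff framework is involved. Evaluation is a pure function of
(parameters, inputs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SirenConfig", "SirenField", "init_siren"]


@dataclass(frozen=True)
class SirenConfig:
    """Architecture settings for a :class:`SirenField`.

    ``n_hidden_layers`` counts sine layers; a linear output layer follows.
    ``output_scale`` is in voxel units per axis: the raw network output is
    multiplied by it, so an O(1) raw output corresponds to a displacement of
    O(output_scale) voxels.
    """

    n_hidden_layers: int = 4
    width: int = 256
    omega0: float = 48.0
    time_dependent: bool = False
    output_scale: tuple[float, float, float] = (2.0, 2.0, 2.0)

    @property
    def in_dim(self) -> int:
        return 4 if self.time_dependent else 3


class SirenField:
    """A Siren network holding its parameters and forward/backward machinery.

    Parameters are a flat list of (W, b) pairs, W of shape (fan_out, fan_in).
    """

    out_dim = 3

    def __init__(self, config: SirenConfig, seed: int = 0):
        if config.width < 1 or config.n_hidden_layers < 1:
            raise ValueError("width and n_hidden_layers must be positive")
        scale = np.asarray(config.output_scale, dtype=np.float64).reshape(3)
        if np.any(scale <= 0):
            raise ValueError("output_scale must be strictly positive")
        self.config = config
        self.seed = int(seed)
        self.output_scale = scale
        self.params = self._init_params(config, self.seed)

    # ------------------------------------------------------------------
    # initialization
    @staticmethod
    def _init_params(cfg: SirenConfig, seed: int) -> list[np.ndarray]:
        rng = np.random.default_rng(seed)
        params: list[np.ndarray] = []
        fan_in = cfg.in_dim
        for layer in range(cfg.n_hidden_layers):
            if layer == 0:
                bound = 1.0 / fan_in
            else:
                bound = np.sqrt(6.0 / fan_in) / cfg.omega0
            W = rng.uniform(-bound, bound, size=(cfg.width, fan_in))
            b = rng.uniform(-bound, bound, size=cfg.width)
            params.extend([W, b])
            fan_in = cfg.width
        bound = np.sqrt(6.0 / fan_in) / cfg.omega0
        Wo = rng.uniform(-bound, bound, size=(SirenField.out_dim, fan_in))
        bo = rng.uniform(-bound, bound, size=SirenField.out_dim)
        params.extend([Wo, bo])
        return params

    @property
    def time_dependent(self) -> bool:
        return self.config.time_dependent

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def zero_grads(self) -> list[np.ndarray]:
        return [np.zeros_like(p) for p in self.params]

    def copy(self) -> "SirenField":
        f = SirenField.__new__(SirenField)
        f.config = self.config
        f.seed = self.seed
        f.output_scale = self.output_scale.copy()
        f.params = [p.copy() for p in self.params]
        return f

    # ------------------------------------------------------------------
    # forward / backward
    def forward(self, X: np.ndarray, want_tape: bool = False):
        """Raw forward pass on (N, in_dim) inputs; returns (N, 3) scaled output.

        With ``want_tape`` the per-layer pre-activations and activations are
        returned for a subsequent :meth:`backward` call.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.config.in_dim:
            raise ValueError(
                f"expected (N, {self.config.in_dim}) inputs, got shape {X.shape}"
            )
        omega0 = self.config.omega0
        acts = [X]
        pres = []
        z = X
        nh = self.config.n_hidden_layers
        for layer in range(nh):
            W, b = self.params[2 * layer], self.params[2 * layer + 1]
            pre = z @ W.T + b
            z = np.sin(omega0 * pre)
            if want_tape:
                pres.append(pre)
                acts.append(z)
        Wo, bo = self.params[2 * nh], self.params[2 * nh + 1]
        out = (z @ Wo.T + bo) * self.output_scale
        if want_tape:
            return out, (acts, pres)
        return out

    def backward(self, tape, d_out: np.ndarray, grads: list[np.ndarray] | None = None):
        """Reverse-mode pass. ``d_out`` is dL/d(scaled output), shape (N, 3).

        Accumulates parameter gradients into ``grads`` (if given) and returns
        (grads, d_input) where d_input is dL/dX, shape (N, in_dim).
        """
        acts, pres = tape
        omega0 = self.config.omega0
        nh = self.config.n_hidden_layers
        if grads is None:
            grads = self.zero_grads()
        g = np.asarray(d_out, dtype=np.float64) * self.output_scale  # dL/d(raw out)
        Wo = self.params[2 * nh]
        grads[2 * nh] += g.T @ acts[nh]
        grads[2 * nh + 1] += g.sum(axis=0)
        g = g @ Wo
        for layer in range(nh - 1, -1, -1):
            W = self.params[2 * layer]
            dpre = g * (omega0 * np.cos(omega0 * pres[layer]))
            grads[2 * layer] += dpre.T @ acts[layer]
            grads[2 * layer + 1] += dpre.sum(axis=0)
            g = dpre @ W
        return grads, g

    def input_jacobian(self, X: np.ndarray) -> np.ndarray:
        """Exact Jacobian of the scaled output w.r.t. the inputs.

        Returns (N, 3, in_dim): one reverse pass per output component.
        """
        X = np.asarray(X, dtype=np.float64)
        _, tape = self.forward(X, want_tape=True)
        n = X.shape[0]
        J = np.empty((n, 3, self.config.in_dim))
        for c in range(3):
            seed = np.zeros((n, 3))
            seed[:, c] = 1.0
            _, d_in = self.backward(tape, seed, grads=self.zero_grads())
            J[:, c, :] = d_in
        return J

    # ------------------------------------------------------------------
    # public evaluation API
    def eval_displacement(self, x: np.ndarray) -> np.ndarray:
        """Displacement (voxel units) at normalized points x, shape (N, 3).

        Only valid for a spatial-only (time-independent) field.
        """
        if self.time_dependent:
            raise ValueError("eval_displacement requires a time-independent field")
        return self.forward(np.atleast_2d(np.asarray(x, dtype=np.float64)))

    def eval_velocity(self, x: np.ndarray, t: float) -> np.ndarray:
        """Velocity (voxel units per unit time) at normalized points x, time t.

        The time coordinate is rescaled to 2t - 1 before entering the network.
        For a time-independent field t is ignored.
        """
        t = float(t)
        if not np.isfinite(t):
            raise ValueError("t must be finite")
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if not self.time_dependent:
            return self.forward(x)
        tcol = np.full((x.shape[0], 1), 2.0 * t - 1.0)
        return self.forward(np.concatenate([x, tcol], axis=1))

    # ------------------------------------------------------------------
    # persistence: flat named-array archive + JSON sidecar
    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "n_hidden_layers": self.config.n_hidden_layers,
            "width": self.config.width,
            "omega0": self.config.omega0,
            "time_dependent": self.config.time_dependent,
            "output_scale": list(map(float, self.output_scale)),
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "SirenField":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = SirenConfig(
            n_hidden_layers=meta["n_hidden_layers"],
            width=meta["width"],
            omega0=meta["omega0"],
            time_dependent=meta["time_dependent"],
            output_scale=tuple(meta["output_scale"]),
        )
        field = cls(cfg, seed=meta["seed"])
        with np.load(path.with_suffix(".npz")) as npz:
            field.params = [npz[f"p{i}"].copy() for i in range(len(npz.files))]
        return field


def init_siren(config: SirenConfig, seed: int) -> SirenField:
    """Create a freshly initialized SirenField (deterministic given seed)."""
    return SirenField(config, seed=seed)
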