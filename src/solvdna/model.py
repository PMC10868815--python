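"""Equivariant prediction of density-fitting coefficients.

The model maps an atomic structure to the population-normalised
coefficients of every auxiliary-basis function.  It is an equivariant
linear model in the style of an atomic cluster expansion: for atom i and
output degree l, neighbour atoms j contribute features

    phi[l, e, n, m](i) = sum_{j in element e, d_ij <= cutoff}
                         B_n(d_ij) * S_lm(r_ij / d_ij),

where B_n are radial basis functions (Gaussian bumps under a cosine
cutoff envelope) and S_lm the real solid harmonics of the unit bond
vector.  The coefficient of shell k (degree l) of an element-E atom is a
learned scalar combination of that atom's degree-l features (plus a bias
for l=0):

    C[i, k, m] = sum_{e, n} W[E, k][e, n] * phi[l, e, n, m](i)  (+ b[E, k]).

Because the features transform exactly like the real-harmonic output
blocks and the weights are scalars, predictions are equivariant to
rotation, translation and atom permutation by construction, not by
training.  The quadratic coefficient-MSE loss can be minimised exactly
per output block by ridge-regularised normal equations (the default
solver) or iteratively with a hand-rolled Adam optimiser for larger
configurations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np

from .basis import AuxBasis
from .density import DensityCoefficients
from .elements import VOCABULARIES
from .harmonics import solid_harmonics
from .structure import Role, Structure


# ---------------------------------------------------------------------------
@dataclass
class AtomGraph:
    """Neighbour graph of a structure within a radial cutoff."""

    one_hot: np.ndarray      # (n_atoms, n_vocab)
    positions: np.ndarray    # (n_atoms, 3) Angstrom
    edges: np.ndarray        # (n_edges, 2) with i < j
    displacements: np.ndarray  # (n_edges, 3) r_j - r_i, Angstrom


def vocabulary_symbol(atom, vocabulary: tuple[str, ...]) -> str:
    """Model element type of an atom; water H/O map to HW/OW in the
    distinct-waters vocabulary."""
    sym = atom.element.symbol
    if "OW" in vocabulary and atom.role is Role.WATER:
        return {"H": "HW", "O": "OW"}[sym]
    return sym


def build_graph(structure: Structure, cutoff: float, vocabulary: str | tuple[str, ...] = "general") -> AtomGraph:
    """One-hot node features and all undirected edges with 0 < d <= cutoff."""
    vocab = VOCABULARIES[vocabulary] if isinstance(vocabulary, str) else tuple(vocabulary)
    n = len(structure)
    one_hot = np.zeros((n, len(vocab)))
    for i, atom in enumerate(structure.atoms):
        sym = vocabulary_symbol(atom, vocab)
        if sym not in vocab:
            raise ValueError(f"Element {sym!r} of atom {i} is not in the model vocabulary {vocab}.")
        one_hot[i, vocab.index(sym)] = 1.0
    pos = structure.positions
    diff = pos[None, :, :] - pos[:, None, :]
    d = np.linalg.norm(diff, axis=-1)
    ii, jj = np.where((d > 0) & (d <= cutoff))
    mask = ii < jj
    edges = np.stack([ii[mask], jj[mask]], axis=-1)
    return AtomGraph(one_hot, pos, edges, diff[edges[:, 0], edges[:, 1]] if len(edges) else np.zeros((0, 3)))


# ---------------------------------------------------------------------------
@dataclass
class ModelConfig:
    """Hyperparameters of the coefficient-prediction model."""

    vocabulary: str = "general"        # "general" (7 types) or "distinct_waters" (9)
    cutoff: float = 3.5                # Angstrom, neighbour cutoff
    n_radial: int = 8                  # radial basis functions per element pair
    solver: str = "lstsq"              # "lstsq" (exact) or "adam"
    ridge: float = 1e-8                # Tikhonov strength for the exact solver
    learning_rate: float = 1e-2        # Adam step size
    batch_size: int = 8                # structures per Adam step
    epochs: int = 200
    seed: int = 0

    def vocab(self) -> tuple[str, ...]:
        return VOCABULARIES[self.vocabulary]


def _radial_basis(d: np.ndarray, cutoff: float, n_radial: int) -> np.ndarray:
    """Gaussian-bump radial basis under a smooth cosine cutoff, (n_edges, n_radial)."""
    centers = np.linspace(0.0, cutoff, n_radial)
    width = cutoff / max(n_radial - 1, 1)
    env = 0.5 * (1.0 + np.cos(np.pi * np.clip(d, 0, cutoff) / cutoff))
    return np.exp(-((d[:, None] - centers[None, :]) ** 2) / (2 * width**2)) * env[:, None]


def _atom_features(structure: Structure, config: ModelConfig) -> dict[int, np.ndarray]:
    """Per-degree feature tensors: l -> (n_atoms, n_vocab * n_radial, 2l+1)."""
    vocab = config.vocab()
    graph = build_graph(structure, config.cutoff, vocab)
    n = len(structure)
    nf = len(vocab) * config.n_radial
    feats = {l: np.zeros((n, nf, 2 * l + 1)) for l in (0, 1, 2)}
    if len(graph.edges) == 0:
        return feats
    d = np.linalg.norm(graph.displacements, axis=-1)
    radial = _radial_basis(d, config.cutoff, config.n_radial)  # (ne, nr)
    unit = graph.displacements / d[:, None]
    harm = {l: solid_harmonics(l, unit) for l in (0, 1, 2)}    # (ne, 2l+1)
    elem_idx = np.argmax(graph.one_hot, axis=1)
    nr = config.n_radial
    for (i, j), rb, k in zip(graph.edges, radial, range(len(d))):
        for src, dst, sign in ((j, i, +1.0), (i, j, -1.0)):
            e = elem_idx[src]
            block = slice(e * nr, (e + 1) * nr)
            for l in (0, 1, 2):
                # odd degrees flip sign with the bond direction
                s = sign if l % 2 else 1.0
                feats[l][dst, block, :] += np.outer(rb, s * harm[l][k])
    return feats


# ---------------------------------------------------------------------------
class TrainedModel:
    """A trained coefficient model: config, per-(element, shell) weights."""

    def __init__(
        self,
        config: ModelConfig,
        basis: AuxBasis,
        weights: dict[str, np.ndarray],
        biases: dict[str, float],
        history: list[float] | None = None,
    ):
        self.config = config
        self.basis = basis
        self.weights = weights   # key "E:k" -> (n_features,) array
        self.biases = biases     # key "E:k" -> float (l=0 shells only)
        self.history = list(history or [])
        self._validate()

    def _validate(self) -> None:
        for sym in self.config.vocab():
            base_sym = {"HW": "H", "OW": "O"}.get(sym, sym)
            for k, shell in enumerate(self.basis.shells(base_sym)):
                key = f"{sym}:{k}"
                if key not in self.weights:
                    raise ValueError(f"Model weights missing output block {key} (l={shell.l}).")

    # -- persistence ---------------------------------------------------
    def vocabulary_hash(self) -> str:
        payload = json.dumps([self.config.vocabulary, self.basis.to_dict()], sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "solvdna-model-1",
            "config": self.config.__dict__,
            "basis": self.basis.to_dict(),
            "vocabulary_hash": self.vocabulary_hash(),
            "weights": {k: v.tolist() for k, v in self.weights.items()},
            "biases": self.biases,
            "history": self.history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        from .basis import _basis_from_dict

        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "solvdna-model-1":
            raise ValueError(f"{path} is not a solvdna model checkpoint.")
        config = ModelConfig(**payload["config"])
        basis = _basis_from_dict(payload["basis"])
        model = cls(
            config,
            basis,
            {k: np.array(v) for k, v in payload["weights"].items()},
            payload["biases"],
            payload["history"],
        )
        if model.vocabulary_hash() != payload["vocabulary_hash"]:
            raise ValueError("Checkpoint vocabulary/basis hash mismatch; refusing to load.")
        return model


def predict_coefficients(model: TrainedModel, structure: Structure) -> DensityCoefficients:
    """Predict population-normalised coefficients for a structure."""
    config = model.config
    vocab = config.vocab()
    feats = _atom_features(structure, config)
    template = DensityCoefficients(
        structure, model.basis, np.zeros(DensityCoefficients.n_functions(structure, model.basis)),
        normalized=True,
    )
    values = template.values
    for i, atom, shell, sl in template.iter_blocks():
        sym = vocabulary_symbol(atom, vocab)
        base_sym = {"HW": "H", "OW": "O"}.get(sym, sym)
        k = model.basis.shells(base_sym).index(shell)
        key = f"{sym}:{k}"
        w = model.weights[key]
        values[sl] = w @ feats[shell.l][i]
        if shell.l == 0:
            values[sl] += model.biases.get(key, 0.0)
    return DensityCoefficients(structure, model.basis, values, normalized=True)


# ---------------------------------------------------------------------------
def _collect_blocks(
    dataset: list[tuple[Structure, DensityCoefficients]],
    config: ModelConfig,
    basis: AuxBasis,
):
    """Group (features, targets) rows by output block key "E:k"."""
    vocab = config.vocab()
    rows: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for structure, target in dataset:
        if not target.normalized:
            raise ValueError("Training targets must be population-normalised coefficients.")
        if target.basis != basis:
            raise ValueError("Training target basis differs from the model basis.")
        feats = _atom_features(structure, config)
        for i, atom, shell, sl in target.iter_blocks():
            sym = vocabulary_symbol(atom, vocab)
            base_sym = {"HW": "H", "OW": "O"}.get(sym, sym)
            k = basis.shells(base_sym).index(shell)
            rows.setdefault(f"{sym}:{k}", []).append((feats[shell.l][i], target.values[sl]))
    return rows


def _mse(model: TrainedModel, dataset) -> float:
    errs = []
    for structure, target in dataset:
        pred = predict_coefficients(model, structure)
        errs.append(np.mean((pred.values - target.values) ** 2))
    return float(np.mean(errs))


def train_model(
    dataset: list[tuple[Structure, DensityCoefficients]],
    config: ModelConfig,
    basis: AuxBasis | None = None,
) -> TrainedModel:
    """Fit the model to (structure, normalised coefficients) pairs.

    The loss is the mean squared error of the output coefficients against
    the training coefficients.  ``solver='lstsq'`` minimises it exactly
    per output block via ridge-regularised normal equations;
    ``solver='adam'`` runs seeded minibatch Adam and records the loss per
    epoch.
    """
    if not dataset:
        raise ValueError("train_model needs a non-empty dataset.")
    basis = basis or dataset[0][1].basis
    rows = _collect_blocks(dataset, config, basis)
    weights: dict[str, np.ndarray] = {}
    biases: dict[str, float] = {}
    nf = len(config.vocab()) * config.n_radial

    # initialise every output block (zeros; blocks without training rows,
    # e.g. elements absent from the dataset, stay at zero)
    for sym in config.vocab():
        base_sym = {"HW": "H", "OW": "O"}.get(sym, sym)
        for k, shell in enumerate(basis.shells(base_sym)):
            key = f"{sym}:{k}"
            weights[key] = np.zeros(nf)
            if shell.l == 0:
                biases[key] = 0.0

    if config.solver == "lstsq":
        for key, data in rows.items():
            X = np.stack([f for f, _ in data])        # (rows, nf, 2l+1)
            Y = np.stack([y for y, _ in [(y, None) for _, y in data]])  # (rows, 2l+1)
            has_bias = key in biases
            Xf = np.swapaxes(X, 1, 2).reshape(-1, nf)  # (rows*(2l+1), nf)
            Yf = Y.reshape(-1)
            if has_bias:
                Xf = np.hstack([Xf, np.ones((len(Xf), 1))])
            G = Xf.T @ Xf + config.ridge * np.eye(Xf.shape[1])
            b = Xf.T @ Yf
            sol = np.linalg.solve(G, b)
            if has_bias:
                weights[key], biases[key] = sol[:-1], float(sol[-1])
            else:
                weights[key] = sol
        model = TrainedModel(config, basis, weights, biases)
        model.history = [_mse(model, dataset)]
        return model

    if config.solver != "adam":
        raise ValueError(f"Unknown solver {config.solver!r}; use 'lstsq' or 'adam'.")

    rng = np.random.default_rng(config.seed)
    m1 = {k: np.zeros(nf + (1 if k in biases else 0)) for k in rows}
    m2 = {k: np.zeros(nf + (1 if k in biases else 0)) for k in rows}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = []
    keys = sorted(rows)
    for epoch in range(config.epochs):
        epoch_loss = 0.0
        count = 0
        for key in keys:
            data = rows[key]
            order = rng.permutation(len(data))
            has_bias = key in biases
            for start in range(0, len(data), config.batch_size):
                batch = [data[t] for t in order[start : start + config.batch_size]]
                X = np.stack([np.swapaxes(f, 0, 1) for f, _ in batch]).reshape(-1, nf)
                Y = np.stack([y for _, y in batch]).reshape(-1)
                if has_bias:
                    X = np.hstack([X, np.ones((len(X), 1))])
                    theta = np.append(weights[key], biases[key])
                else:
                    theta = weights[key]
                resid = X @ theta - Y
                grad = 2.0 * X.T @ resid / len(Y)
                step += 1
                m1[key] = beta1 * m1[key] + (1 - beta1) * grad
                m2[key] = beta2 * m2[key] + (1 - beta2) * grad**2
                mh = m1[key] / (1 - beta1**step)
                vh = m2[key] / (1 - beta2**step)
                theta = theta - config.learning_rate * mh / (np.sqrt(vh) + eps)
                if has_bias:
                    weights[key], biases[key] = theta[:-1], float(theta[-1])
                else:
                    weights[key] = theta
                epoch_loss += float(np.mean(resid**2)) * len(Y)
                count += len(Y)
        loss = epoch_loss / max(count, 1)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"Training loss became non-finite at epoch {epoch}; "
                f"reduce learning_rate (currently {config.learning_rate})."
            )
        history.append(loss)
    return TrainedModel(config, basis, weights, biases, history)
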