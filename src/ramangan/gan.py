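"""Per-class vanilla GAN for Raman spectra, plus the augmentation strategies.

One independent GAN is trained per tissue class. The generator maps a
standard-normal latent vector to a spectrum through fully connected layers
(100, 64, 64, 64 hidden units, each followed by batch normalization, ReLU
activations) with a sigmoid output on min-max-scaled intensities; the
discriminator is a fully connected net (first hidden layer as wide as the
input dimension, then 64, 64; leaky-ReLU activations) ending in a single
sigmoid probability unit. Training alternates k discriminator ascent steps
with one generator descent step on the minimax value

    V(G, D) = E_x[log D(x)] + E_z[log(1 - D(G(z)))],

the generator minimizing E_z[log(1 - D(G(z)))] (the saturating form; a
non-saturating option that maximizes E_z[log D(G(z))] is available but off
by default). Probabilities are clamped to [eps, 1-eps] inside the logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._nn import (
    EPS,
    Adam,
    BatchNorm,
    Dense,
    LeakyReLU,
    ReLU,
    Sequential,
    Sigmoid,
    minibatches,
)
from .dataset import SpectraDataset
from .scaling import SpectrumScaler

__all__ = [
    "GanConfig",
    "SpectrumGAN",
    "discriminator_value",
    "generator_value",
    "minimax_value",
    "train_gan",
    "sample_synthetic",
    "augment_balanced",
    "augment_stratified",
]


@dataclass
class GanConfig:
    """Hyperparameters of one per-class GAN.

    ``disc_hidden=None`` means "first hidden layer as wide as the input
    dimension d, then 64, 64" — at d=1608 this is the (1608, 64, 64) stack.
    """

    latent_dim: int = 100
    gen_hidden: tuple[int, ...] = (100, 64, 64, 64)
    disc_hidden: tuple[int, ...] | None = None
    epochs: int = 500
    learning_rate: float = 2e-4
    disc_steps: int = 1  # k in the alternating scheme
    batch_size: int = 32  # effective batch = min(batch_size, class size)
    prob_clamp: float = EPS
    non_saturating: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or any(w < 1 for w in self.gen_hidden):
            raise ValueError("layer widths must be >= 1")
        if self.disc_hidden is not None and any(w < 1 for w in self.disc_hidden):
            raise ValueError("layer widths must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.disc_steps < 1:
            raise ValueError("disc_steps (k) must be >= 1")
        if not (0 < self.prob_clamp < 0.5):
            raise ValueError("prob_clamp must be in (0, 0.5)")


def _clamp(p: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)


def discriminator_value(d_on_real, d_on_fake, eps: float = EPS) -> float:
    """Discriminator objective: mean log D(x) + mean log(1 - D(G(z))).

    Always <= 2*log(1-eps); equals -2 ln 2 for an uninformative D(.)=0.5.
    """
    d_on_real = np.asarray(d_on_real, dtype=float)
    d_on_fake = np.asarray(d_on_fake, dtype=float)
    if d_on_real.size == 0 or d_on_fake.size == 0:
        raise ValueError("probability lists must be non-empty")
    if d_on_real.min() < 0 or d_on_real.max() > 1 or d_on_fake.min() < 0 or d_on_fake.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(
        np.mean(np.log(_clamp(d_on_real, eps)))
        + np.mean(np.log(1.0 - _clamp(d_on_fake, eps)))
    )


def generator_value(d_on_fake, eps: float = EPS) -> float:
    """Generator objective (saturating form): mean log(1 - D(G(z)))."""
    d_on_fake = np.asarray(d_on_fake, dtype=float)
    if d_on_fake.size == 0:
        raise ValueError("probability list must be non-empty")
    if d_on_fake.min() < 0 or d_on_fake.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean(np.log(1.0 - _clamp(d_on_fake, eps))))


def minimax_value(d_on_real, d_on_fake, eps: float = EPS) -> float:
    """The two-player minimax value; same closed form as the discriminator
    objective (the generator controls only the second expectation)."""
    return discriminator_value(d_on_real, d_on_fake, eps)


class SpectrumGAN(BaseEstimator):
    """Vanilla GAN over min-max-scaled spectra of a single class.

    Follows the scikit-learn estimator protocol: ``fit(X)`` trains on an
    (n, d) intensity matrix, ``sample(n, random_state)`` draws synthetic
    spectra inverse-scaled back to original intensity units.

    Fitted attributes
    -----------------
    generator_, discriminator_ : trained networks
    scaler_ : the min-max scaler fitted on the training class
    history_ : dict with per-epoch ``disc_value`` and ``gen_value`` lists
    """

    def __init__(self, config: GanConfig | None = None, class_label: str = ""):
        self.config = config
        self.class_label = class_label

    def _build(self, d: int, rng: np.random.Generator, cfg: GanConfig) -> None:
        layers: list = []
        n_in = cfg.latent_dim
        for width in cfg.gen_hidden:
            layers += [Dense(n_in, width, rng), BatchNorm(width), ReLU()]
            n_in = width
        layers += [Dense(n_in, d, rng), Sigmoid()]
        self.generator_ = Sequential(layers)

        disc_hidden = cfg.disc_hidden if cfg.disc_hidden is not None else (d, 64, 64)
        layers = []
        n_in = d
        for width in disc_hidden:
            layers += [Dense(n_in, width, rng), LeakyReLU(0.2)]
            n_in = width
        # the net outputs the logit; the sigmoid is applied outside so loss
        # gradients are taken at the logit (numerically stable, never clipped)
        layers += [Dense(n_in, 1, rng)]
        self.discriminator_ = Sequential(layers)

    def _disc_prob(self, x: np.ndarray, train: bool) -> np.ndarray:
        logit = self.discriminator_.forward(x, train=train).ravel()
        return 1.0 / (1.0 + np.exp(-np.clip(logit, -60, 60)))

    def fit(self, X, y=None):
        cfg = self.config if self.config is not None else GanConfig()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("GAN training requires an (n>=2, d) intensity matrix")
        rng = np.random.default_rng(cfg.seed)
        d = X.shape[1]
        self.scaler_ = SpectrumScaler("minmax01").fit(X)
        Xs = self.scaler_.transform(X)
        self._build(d, rng, cfg)

        g_params = self.generator_.params()
        d_params = self.discriminator_.params()
        g_opt = Adam(g_params, lr=cfg.learning_rate)
        d_opt = Adam(d_params, lr=cfg.learning_rate)
        eps = cfg.prob_clamp
        batch = min(cfg.batch_size, X.shape[0])
        self.history_ = {"disc_value": [], "gen_value": []}

        for _ in range(cfg.epochs):
            dv_epoch, gv_epoch = [], []
            for idx in minibatches(X.shape[0], batch, rng):
                real = Xs[idx]
                m = real.shape[0]
                # --- k discriminator ascent steps -------------------------
                # gradients are taken at the logit:
                #   d(-log sigma(l))/dl = p - 1;  d(-log(1 - sigma(l)))/dl = p
                for _k in range(cfg.disc_steps):
                    z = rng.standard_normal((m, cfg.latent_dim))
                    fake = self.generator_.forward(z, train=True)
                    d_opt.zero_grad()
                    p_real = self._disc_prob(real, train=True)
                    self.discriminator_.backward((p_real - 1.0)[:, None] / m)
                    p_fake = self._disc_prob(fake, train=True)
                    self.discriminator_.backward(p_fake[:, None] / m)
                    d_opt.step()
                    dv_epoch.append(
                        discriminator_value(p_real, p_fake, eps)
                    )
                # --- one generator descent step ---------------------------
                z = rng.standard_normal((m, cfg.latent_dim))
                fake = self.generator_.forward(z, train=True)
                p_fake = self._disc_prob(fake, train=True)
                g_opt.zero_grad()
                d_opt.zero_grad()  # discriminator only relays gradient here
                if cfg.non_saturating:
                    # descend -mean log D(G(z)):  d/dl = p - 1
                    dlogit = (p_fake - 1.0) / m
                else:
                    # descend mean log(1 - D(G(z))):  d/dl = -p
                    dlogit = -p_fake / m
                grad_to_g = self.discriminator_.backward(dlogit[:, None])
                self.generator_.backward(grad_to_g)
                g_opt.step()
                d_opt.zero_grad()
                gv_epoch.append(generator_value(p_fake, eps))
            if dv_epoch:
                self.history_["disc_value"].append(float(np.mean(dv_epoch)))
                self.history_["gen_value"].append(float(np.mean(gv_epoch)))
        self.n_features_in_ = d
        return self

    def sample(self, n: int, random_state=None) -> np.ndarray:
        """Draw n synthetic spectra in original intensity units (eval-mode
        batch statistics, deterministic given random_state)."""
        if n < 0:
            raise ValueError("n must be >= 0")
        cfg = self.config if self.config is not None else GanConfig()
        if n == 0:
            return np.empty((0, self.n_features_in_))
        rng = np.random.default_rng(random_state)
        z = rng.standard_normal((n, cfg.latent_dim))
        scaled = self.generator_.forward(z, train=False)
        return self.scaler_.inverse_transform(scaled)


# ---------------------------------------------------------------------------
# dataset-level wrappers


def train_gan(class_data: SpectraDataset, cfg: GanConfig | None = None) -> SpectrumGAN:
    """Train one GAN on a single-class dataset."""
    labels = set(class_data.labels)
    if len(labels) > 1:
        raise ValueError(f"train_gan expects a single class, got {sorted(labels)}")
    if class_data.n < 2:
        raise ValueError("GAN training requires at least 2 samples")
    label = next(iter(labels))
    model = SpectrumGAN(config=cfg, class_label=label)
    model.fit(class_data.X)
    model.axis_ = class_data.axis
    return model


def sample_synthetic(model: SpectrumGAN, n: int, random_state=None,
                     id_prefix: str | None = None) -> SpectraDataset:
    """Draw n synthetic samples as a dataset (synthetic flag set, treatment
    flag unknown, intensities in original units). The model must have been
    trained through :func:`train_gan` so it carries the spectral axis."""
    axis = getattr(model, "axis_", None)
    if axis is None:
        raise ValueError("model carries no spectral axis; train it via train_gan")
    X = model.sample(n, random_state)
    label = model.class_label or "synthetic"
    prefix = id_prefix if id_prefix is not None else f"{label}_gan"
    return SpectraDataset(
        axis=axis,
        X=X,
        labels=np.array([label] * n, dtype=object),
        treated=np.array(["unknown"] * n, dtype=object),
        sample_ids=np.array([f"{prefix}_{i:04d}" for i in range(n)], dtype=object),
        synthetic=np.ones(n, dtype=bool),
        class_set=(label,),
    )


def _synthetic_for_class(
    original: SpectraDataset,
    models: dict[str, SpectrumGAN],
    label: str,
    n_new: int,
    random_state,
) -> SpectraDataset:
    if label not in models:
        raise ValueError(f"no GAN model for class {label!r}")
    X = models[label].sample(n_new, random_state)
    return SpectraDataset(
        axis=original.axis,
        X=X,
        labels=np.array([label] * n_new, dtype=object),
        treated=np.array(["unknown"] * n_new, dtype=object),
        sample_ids=np.array(
            [f"{label}_gan_{i:04d}" for i in range(n_new)], dtype=object
        ),
        synthetic=np.ones(n_new, dtype=bool),
        class_set=original.class_set,
    )


def augment_balanced(
    original: SpectraDataset,
    models: dict[str, SpectrumGAN],
    n_prime: int,
    random_state=None,
) -> SpectraDataset:
    """Balanced augmentation: add exactly n' synthetic samples to every class,
    so class sizes c_k become c_k + n' and the total becomes n + K*n'."""
    if n_prime < 0:
        raise ValueError("n_prime must be >= 0")
    missing = [c for c in original.class_set if c not in models]
    if missing:
        raise ValueError(f"no GAN model for classes {missing}")
    out = original
    ss = np.random.SeedSequence(random_state)
    for label, child in zip(original.class_set, ss.spawn(len(original.class_set))):
        if n_prime:
            out = out.concat(
                _synthetic_for_class(original, models, label, n_prime, child)
            )
    return out


def augment_stratified(
    original: SpectraDataset,
    models: dict[str, SpectrumGAN],
    m: int,
    random_state=None,
) -> SpectraDataset:
    """Stratified augmentation: add m*c_k synthetic samples to each class of
    size c_k, preserving the class prior probabilities exactly."""
    if m < 0:
        raise ValueError("m must be >= 0")
    from .dataset import class_counts

    missing = [c for c in original.class_set if c not in models]
    if missing:
        raise ValueError(f"no GAN model for classes {missing}")
    counts = class_counts(original)
    out = original
    ss = np.random.SeedSequence(random_state)
    for label, child in zip(original.class_set, ss.spawn(len(original.class_set))):
        n_new = m * counts[label]
        if n_new:
            out = out.concat(
                _synthetic_for_class(original, models, label, n_new, child)
            )
    return out
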