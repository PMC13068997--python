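"""Synthetic federated cohorts with controllable label skew and site shift.

Each client (site) draws class-conditional Gaussian features and then
passes them through a site-specific affine transform,

    x = A_k (mu_y + eps) + c_k,      eps ~ N(0, I),

where ``mu_1 - mu_0`` has norm ``class_separation``, ``A_k = I +
shift_strength * R_k`` with ``R_k`` a seeded random matrix scaled to unit
spectral norm, and ``c_k`` a seeded random offset of norm
``shift_strength``.  The affine site transform is the simplest mechanism
that produces genuine representation-level divergence between clients
(different decision boundaries in raw feature space) while leaving the
within-site task unchanged; ``shift_strength`` is the single heterogeneity
dial.  Label counts are deterministic (``round(prevalence * n)``), so the
label-discrepancy term of the aggregation rule is exactly controllable.

``three_site_cohort`` mirrors the structure of a three-hospital pancreatic
cancer cohort: sizes 180/163/203 (546 patients), positive-class prevalences
0.71/0.69/0.64, and stratified 70/10/20 train/val/test splits per site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import LabelDistribution

__all__ = [
    "ScenarioSpec",
    "ClientData",
    "FederatedDataset",
    "make_scenario",
    "three_site_cohort",
    "empirical_label_distribution",
    "largest_remainder",
]

SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class ScenarioSpec:
    client_sizes: tuple[int, ...]
    prevalences: tuple[float, ...]
    feature_dim: int = 16
    class_separation: float = 1.0
    shift_strength: float = 0.5
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0
    client_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "client_sizes", tuple(int(n) for n in self.client_sizes))
        object.__setattr__(self, "prevalences", tuple(float(p) for p in self.prevalences))
        if len(self.client_sizes) != len(self.prevalences):
            raise ValueError("client_sizes and prevalences must have equal length")
        if len(self.client_sizes) < 2:
            raise ValueError("a federation needs at least 2 clients")
        if any(not 0.0 < p < 1.0 for p in self.prevalences):
            raise ValueError("prevalences must lie strictly in (0, 1)")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if self.client_names is None:
            object.__setattr__(
                self,
                "client_names",
                tuple(f"site{i + 1}" for i in range(len(self.client_sizes))),
            )
        elif len(self.client_names) != len(self.client_sizes):
            raise ValueError("client_names length mismatch")

    @property
    def n_clients(self) -> int:
        return len(self.client_sizes)


@dataclass
class ClientData:
    name: str
    X: np.ndarray  # (n, d) features
    y: np.ndarray  # (n,) binary labels
    split: np.ndarray  # (n,) strings in {"train", "val", "test"}

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.split == which
        return self.X[mask], self.y[mask]

    @property
    def n(self) -> int:
        return int(self.y.size)


@dataclass
class FederatedDataset:
    clients: list[ClientData]
    spec: ScenarioSpec

    @property
    def feature_dim(self) -> int:
        return int(self.clients[0].X.shape[1])

    def pooled(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """Union of one split across all clients."""
        Xs, ys = zip(*(c.subset(which) for c in self.clients))
        return np.concatenate(Xs), np.concatenate(ys)

    def save(self, directory: str | Path) -> None:
        """Serialize to per-client CSV tables plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = asdict(self.spec)
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for c in self.clients:
            df = pd.DataFrame(c.X, columns=[f"f{j}" for j in range(c.X.shape[1])])
            df["label"] = c.y
            df["split"] = c.split
            df.to_csv(directory / f"{c.name}.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "FederatedDataset":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        for key in ("client_sizes", "prevalences", "split_fractions", "client_names"):
            if manifest.get(key) is not None:
                manifest[key] = tuple(manifest[key])
        spec = ScenarioSpec(**manifest)
        clients = []
        for name in spec.client_names:
            df = pd.read_csv(directory / f"{name}.csv")
            feat_cols = [c for c in df.columns if c.startswith("f")]
            clients.append(
                ClientData(
                    name=name,
                    X=df[feat_cols].to_numpy(dtype=np.float64),
                    y=df["label"].to_numpy(dtype=int),
                    split=df["split"].to_numpy(dtype=object),
                )
            )
        return cls(clients, spec)


def largest_remainder(total: int, fractions: tuple[float, ...]) -> list[int]:
    """Apportion ``total`` into integer parts by the largest-remainder rule.

    Ties in the fractional remainders are broken toward the earlier
    fraction (train before val before test).
    """
    exact = np.asarray(fractions, dtype=np.float64) * total
    base = np.floor(exact).astype(int)
    short = total - base.sum()
    # remainders rounded to 9 decimals so float noise cannot break ties;
    # stable sort: earlier index wins exact ties
    order = np.argsort(-np.round(exact - base, 9), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def _positive_count(prevalence: float, n: int) -> int:
    # round half up, e.g. 0.71 * 180 = 127.8 -> 128
    return int(np.floor(prevalence * n + 0.5))


def make_scenario(spec: ScenarioSpec) -> FederatedDataset:
    """Generate a federated dataset; bit-identical for identical specs."""
    root = np.random.SeedSequence([int(spec.seed), 0xC0_4057])
    shared_rng = np.random.default_rng(root.spawn(1)[0])

    d = spec.feature_dim
    direction = shared_rng.standard_normal(d)
    direction /= np.linalg.norm(direction)
    mu1 = 0.5 * spec.class_separation * direction
    mu0 = -mu1

    clients = []
    for k, (n, prev, name) in enumerate(
        zip(spec.client_sizes, spec.prevalences, spec.client_names)
    ):
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xC0_4057, k]))
        n_pos = _positive_count(prev, n)
        n_neg = n - n_pos
        if n_pos == 0 or n_neg == 0:
            raise ValueError(f"client {name}: a class is empty at size {n}")
        nonzero_splits = sum(1 for f in spec.split_fractions if f > 0)
        if min(n_pos, n_neg) < nonzero_splits:
            raise ValueError(
                f"client {name}: too few samples per class to realize the splits"
            )

        if spec.shift_strength > 0:
            G = rng.standard_normal((d, d))
            A = np.eye(d) + spec.shift_strength * G / np.linalg.norm(G, 2)
            u = rng.standard_normal(d)
            c = spec.shift_strength * u / np.linalg.norm(u)
        else:
            rng.standard_normal((d, d))  # keep the draw schedule stable
            rng.standard_normal(d)
            A = np.eye(d)
            c = np.zeros(d)

        y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
        y = y[rng.permutation(n)]
        eps = rng.standard_normal((n, d))
        mu = np.where(y[:, None] == 1, mu1, mu0)
        X = (mu + eps) @ A.T + c

        split = np.empty(n, dtype=object)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            idx = idx[rng.permutation(idx.size)]
            counts = largest_remainder(idx.size, spec.split_fractions)
            offset = 0
            for which, cnt in zip(SPLITS, counts):
                split[idx[offset : offset + cnt]] = which
                offset += cnt
        clients.append(ClientData(name=name, X=X, y=y, split=split))
    return FederatedDataset(clients, spec)


def three_site_cohort(seed: int = 0, **overrides) -> ScenarioSpec:
    """Preset emulating the three-hospital cohort structure (546 patients)."""
    defaults = dict(
        client_sizes=(180, 163, 203),
        prevalences=(0.71, 0.69, 0.64),
        feature_dim=16,
        class_separation=1.0,
        shift_strength=0.5,
        split_fractions=(0.7, 0.1, 0.2),
        seed=seed,
    )
    defaults.update(overrides)
    return ScenarioSpec(**defaults)


def empirical_label_distribution(labels, n_classes: int = 2) -> LabelDistribution:
    """Class frequencies of a label vector."""
    return LabelDistribution.from_labels(labels, n_classes=n_classes)
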