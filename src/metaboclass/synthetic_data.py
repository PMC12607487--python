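"""Synthetic class-structured relative-abundance tables and bioactivity
fixtures.

The generator emulates the statistical shape of a two-cultivar GC/MS
profiling design: 12 samples (two classes x three extract types), 61
compositional features of which exactly 13 are "major" (>= 10% relative
abundance in at least one sample) and the rest are minor noise, and a small
set of class-discriminative features whose separation is controlled in
pooled-standard-deviation units.

Construction: per sample, log-normal raw intensities (major features on a
higher baseline) are closed to percent-of-total. Discriminative features
receive a ± effect_size/2 x sigma log-mean offset by class, alternating
which class is elevated (mirroring a linoleic-acid-high class versus a
clionasterol-high class); each non-discriminative major is additionally
boosted in all samples of one extract type (O, M-H or M-E, assigned round
robin), emulating extract-specific dominant peaks — present in both
classes, so exactly class-symmetric.
After closure, the major/minor split is made deterministic with minimal
intervention: minor features are capped below 10% everywhere, and any
major feature whose maximum falls short of 10% is floored at its maximum
sample (a class-symmetric rule, since that sample is random).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AbundanceTable, SampleClasses

_DISCRIMINATIVE_NAMES = ("linoleic_acid_like", "clionasterol_like", "vitamin_E_like")
_EXTRACTS = ("O", "M-H", "M-E")

# Construction constants (log-intensity space, arbitrary raw units)
_MAJOR_BASE = 12.0     # baseline raw intensity of a major feature
_MINOR_BASE = 1.0      # baseline raw intensity of a minor feature
_EXTRACT_BOOST = 6.0   # multiplicative boost in a feature's dominant extract
_MINOR_CAP = 9.0       # percent ceiling enforced on minor features
_MAJOR_FLOOR = 10.5    # percent floor enforced at home samples


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    effect_size is the class-mean separation of each discriminative feature
    in pooled within-class standard deviations (log-intensity scale);
    sigma is the log-normal noise level.
    """

    n_per_class: int = 6
    n_features: int = 61
    n_major: int = 13
    n_discriminative: int = 3
    effect_size: float = 4.0
    sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_discriminative <= self.n_major <= self.n_features):
            raise ValueError(
                "need 0 < n_discriminative <= n_major <= n_features, got "
                f"{self.n_discriminative}/{self.n_major}/{self.n_features}"
            )
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def _feature_names(config: GeneratorConfig) -> list[str]:
    names = list(_DISCRIMINATIVE_NAMES[: config.n_discriminative])
    names += [f"disc_{i:02d}" for i in range(len(names), config.n_discriminative)]
    names += [f"major_{i:02d}" for i in range(config.n_discriminative, config.n_major)]
    names += [f"minor_{i:02d}" for i in range(config.n_major, config.n_features)]
    return names


def _sample_ids(config: GeneratorConfig) -> tuple[list[str], dict[str, str]]:
    ids, extracts = [], {}
    for prefix in ("HS-TH", "HS-FS"):
        for i in range(config.n_per_class):
            extract = _EXTRACTS[i % 3]
            sid = f"{prefix}-{i // 3 + 1}-{extract}"
            ids.append(sid)
            extracts[sid] = extract
    return ids, extracts


def generate_abundance(config: GeneratorConfig | None = None) -> tuple[AbundanceTable, SampleClasses]:
    """Draw one synthetic abundance table with its class labels.

    Deterministic under ``config.seed``. Guarantees that exactly
    ``n_major`` features reach >= 10% relative abundance in at least one
    sample and that every other feature stays below 10% in all samples, so
    the cutoff-filter stage has a known ground truth.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_class
    n_major, n_feat = config.n_major, config.n_features
    names = _feature_names(config)
    sample_ids, extracts = _sample_ids(config)
    classes = np.array([0] * config.n_per_class + [1] * config.n_per_class)

    # feasibility: a sample can host at most ~9 features pinned at the 10.5%
    # floor, and each major needs one hosting sample in the worst case
    if n_major > 9 * n:
        raise ValueError(
            f"n_major={n_major} is too large for {n} samples: the >=10% "
            f"guarantee cannot hold under compositional closure"
        )

    n_disc = config.n_discriminative
    mu = np.where(np.arange(n_feat) < n_major, np.log(_MAJOR_BASE), np.log(_MINOR_BASE))
    logx = mu[None, :] + config.sigma * rng.standard_normal((n, n_feat))
    # class offsets on discriminative features, alternating elevated class
    half = config.effect_size * config.sigma / 2.0
    for d in range(n_disc):
        elevated = d % 2
        logx[:, d] += np.where(classes == elevated, half, -half)
    # extract-type boosts: each non-discriminative major dominates one
    # extract type, in both classes
    extract_index = np.array([i % 3 for i in range(config.n_per_class)] * 2)
    for j in range(n_disc, n_major):
        boosted = extract_index == (j - n_disc) % 3
        logx[boosted, j] += np.log(_EXTRACT_BOOST)

    raw = np.exp(logx)
    pct = 100.0 * raw / raw.sum(axis=1, keepdims=True)

    # enforcement: cap minors below 10% everywhere ...
    minors = slice(n_major, n_feat)
    for i in range(n):
        row = pct[i]
        excess = np.clip(row[minors] - _MINOR_CAP, 0, None).sum()
        if excess > 0:
            np.clip(row[minors], None, _MINOR_CAP, out=row[minors])
            major_total = row[:n_major].sum()
            row[:n_major] *= (major_total + excess) / major_total
    # ... and floor each shortfall major at its maximum sample; renormalizing
    # a sample can knock another major below threshold there, so iterate.
    floored: dict[int, set[int]] = {}  # sample -> features pinned at the floor
    while True:
        maxima = pct[:, :n_major].max(axis=0)
        need = np.flatnonzero(maxima < 10.0)
        if need.size == 0:
            break
        for j in need:
            i = int(np.argmax(pct[:, j]))
            floored.setdefault(i, set()).add(int(j))
            pinned = sorted(floored[i])
            if len(pinned) * _MAJOR_FLOOR > 95.0:
                raise ValueError("infeasible major-feature floor under closure")
            row = pct[i]
            row[pinned] = _MAJOR_FLOOR
            free = [f for f in range(n_feat) if f not in floored[i]]
            budget = 100.0 - len(pinned) * _MAJOR_FLOOR
            row[free] *= budget / row[free].sum()

    table = AbundanceTable(pd.DataFrame(pct.T, index=names, columns=sample_ids))
    sample_classes = SampleClasses(
        labels=dict(zip(sample_ids, (int(c) for c in classes))),
        class_names={0: "Thai", 1: "Foreign"},
        extract_type=extracts,
    )
    return table, sample_classes


def generate_null_labels(classes: SampleClasses, seed: int = 0) -> SampleClasses:
    """Uniformly random label permutation preserving class sizes."""
    ids = classes.sample_ids
    if len(ids) < 2:
        raise ValueError("need at least two samples to shuffle")
    rng = np.random.default_rng(seed)
    values = rng.permutation([classes.labels[s] for s in ids])
    return SampleClasses(
        labels=dict(zip(ids, (int(v) for v in values))),
        class_names=dict(classes.class_names),
        extract_type=dict(classes.extract_type) if classes.extract_type else None,
    )


def generate_bioactivity_fixture(seed: int = 0):
    """Three single-agent inhibition values near 40% and three pairwise
    combinations with planted integer percent improvements.

    Returns
    -------
    (singles, combos, planted)
        ``planted`` maps (pair, reference agent) to the integer improvement
        planted for the pair's first-listed agent; recovery through
        :func:`metaboclass.bioactivity.build_synergy_table` is exact.
    """
    rng = np.random.default_rng(seed)
    agents = list(_DISCRIMINATIVE_NAMES)
    singles = {a: float(np.round(rng.uniform(38.0, 44.0), 2)) for a in agents}
    combos, planted = {}, {}
    pairs = [(agents[0], agents[1]), (agents[0], agents[2]), (agents[1], agents[2])]
    for pair in pairs:
        improvement = int(rng.integers(25, 116))
        combined = float(np.round(singles[pair[0]] * (1 + improvement / 100.0), 2))
        combos[pair] = combined
        planted[(pair, pair[0])] = improvement
    return singles, combos, planted
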