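"""Synthetic two-group microbiome count data with planted diet-sensitive OTUs.

The generator emulates a multi-trial feeding-study design: several
independent trials, each with a control and a treatment arm of equal size,
sampled at a single day.  Baseline OTU abundances are heavy-tailed
(log-normal across OTUs), library sizes vary between samples, zeros are
inflated, and a chosen subset of OTUs carries a multiplicative fold change
in the treatment arm that is consistent in direction across trials — the
ground truth every downstream stage is checked against.

Counts are produced compositionally: a per-sample relative-abundance vector
is built (baseline × trial effect × treatment effect, zero-inflated,
renormalized) and the sample's reads are drawn from a multinomial at its
library size.  Applying the effect on the composition scale before
renormalization means "increased" OTUs mechanically depress all others a
little — the same closure artefact real 16S data shows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import SAMPLE_ID_TOKEN

#: Phyla observed in broiler cecum surveys, most to least abundant.
DEFAULT_PHYLA_WEIGHTS = {
    "Firmicutes": 0.60,
    "Bacteroidetes": 0.20,
    "Proteobacteria": 0.09,
    "Actinobacteria": 0.05,
    "Cyanobacteria": 0.02,
    "Tenericutes": 0.02,
    "Euryarchaeota": 0.01,
    "Deferribacteres": 0.005,
    "Verrucomicrobia": 0.003,
    "Lentisphaerae": 0.001,
    "Thermotogae": 0.001,
}


class SimulationConfigError(ValueError):
    """A simulation parameter is out of its valid range."""


@dataclass
class SimulationConfig:
    """Study design and noise model for :func:`simulate_community`.

    Defaults mirror the emulated study: 4 trials, 12 birds per shed per
    trial, a community of 500 OTUs, samples taken at day 35.  Library sizes
    (2,000–5,000 reads) are a fixture-scale choice for amplicon data.
    """

    n_trials: int = 4
    n_per_group: int = 12
    n_otus: int = 500
    n_sensitive: int = 10
    effect_sizes: tuple[float, ...] = (4.0, 4.0, 4.0, 4.0, 4.0, 0.25, 0.25, 0.25, 0.25, 0.25)
    base_log_mean: float = 0.0
    base_log_sd: float = 2.0
    zero_inflation: float = 0.1
    library_size_range: tuple[int, int] = (2000, 5000)
    trial_sd: float = 0.2
    day: int = 35
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise SimulationConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.n_per_group < 1:
            raise SimulationConfigError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if self.n_otus < 1:
            raise SimulationConfigError(f"n_otus must be >= 1, got {self.n_otus}")
        if not 0 <= self.n_sensitive <= self.n_otus:
            raise SimulationConfigError(
                f"n_sensitive must be in [0, n_otus], got {self.n_sensitive}"
            )
        if len(self.effect_sizes) != self.n_sensitive:
            raise SimulationConfigError(
                f"effect_sizes must have length n_sensitive={self.n_sensitive}, "
                f"got {len(self.effect_sizes)}"
            )
        if any(e <= 0 or e == 1 for e in self.effect_sizes):
            raise SimulationConfigError("effect_sizes must be > 0 and != 1")
        if not 0 <= self.zero_inflation < 1:
            raise SimulationConfigError(
                f"zero_inflation must be in [0, 1), got {self.zero_inflation}"
            )
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise SimulationConfigError(
                f"library_size_range must satisfy 1 <= min <= max, got {self.library_size_range}"
            )
        if self.base_log_sd < 0 or self.trial_sd < 0:
            raise SimulationConfigError("standard deviations must be >= 0")


@dataclass
class GroundTruth:
    """Planted treatment-sensitive OTUs and their direction of change."""

    sensitive_otu_ids: frozenset[str]
    direction: dict[str, str] = field(default_factory=dict)  # otu_id -> increased/decreased
    effect_size: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.direction) != set(self.sensitive_otu_ids):
            raise ValueError("direction must be defined exactly for sensitive_otu_ids")


def _otu_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"OTU_{i:0{width}d}" for i in range(1, n + 1)]


def simulate_community(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a count table, metadata and ground truth per ``config``.

    The table has ``n_trials * 2 * n_per_group`` rows.  The first
    ``n_sensitive`` OTUs (``OTU_0001`` …) are the planted sensitive set, each
    multiplied by its fold change in the treatment arm of every trial.
    Identical seeds give byte-identical output.

    Randomness is split off a single ``SeedSequence``: one child stream for
    community-level draws (baselines), one per trial (trial offsets), one per
    sample (zero-inflation mask, library size, multinomial) — so enlarging
    the design leaves earlier draws unchanged.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    community_ss, trials_ss, samples_ss = ss.spawn(3)
    rng = np.random.default_rng(community_ss)

    otu_ids = _otu_ids(config.n_otus)
    baseline = rng.lognormal(config.base_log_mean, config.base_log_sd, size=config.n_otus)
    # Sensitive OTUs draw from the upper half of the same log-normal
    # (|N(0,sd)| above the median) so the planted fold change is expressed
    # above the sampling-depth detection floor and empirical group means
    # reliably order with the ground-truth direction.
    if config.n_sensitive:
        baseline[: config.n_sensitive] = np.exp(
            config.base_log_mean
            + np.abs(rng.normal(0.0, config.base_log_sd, size=config.n_sensitive))
        )

    effects = np.ones(config.n_otus)
    effects[: config.n_sensitive] = np.asarray(config.effect_sizes, dtype=float)
    sensitive = otu_ids[: config.n_sensitive]
    truth = GroundTruth(
        sensitive_otu_ids=frozenset(sensitive),
        direction={
            o: ("increased" if e > 1 else "decreased")
            for o, e in zip(sensitive, config.effect_sizes)
        },
        effect_size=dict(zip(sensitive, config.effect_sizes)),
    )

    trial_rngs = [np.random.default_rng(s) for s in trials_ss.spawn(config.n_trials)]
    sample_rng = np.random.default_rng(samples_ss)

    rows, sample_ids, meta_rows = [], [], []
    for t in range(config.n_trials):
        trial = f"T{t + 1}"
        trial_offset = np.exp(trial_rngs[t].normal(0.0, config.trial_sd, size=config.n_otus))
        trial_base = baseline * trial_offset
        for group, grp_code in (("control", "C"), ("treatment", "X")):
            comp_group = trial_base * (effects if group == "treatment" else 1.0)
            for k in range(config.n_per_group):
                comp = comp_group.copy()
                if config.zero_inflation > 0:
                    mask = sample_rng.random(config.n_otus) < config.zero_inflation
                    comp[mask] = 0.0
                total = comp.sum()
                if total == 0:  # pathological zero-inflation draw; keep one OTU
                    comp = comp_group.copy()
                    total = comp.sum()
                comp /= total
                lo, hi = config.library_size_range
                depth = int(sample_rng.integers(lo, hi + 1))
                counts = sample_rng.multinomial(depth, comp)
                rows.append(counts)
                sample_ids.append(f"{trial}{grp_code}{k + 1:02d}")
                meta_rows.append({"trial": trial, "day": config.day, "group": group})

    table = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.Index(sample_ids, name=SAMPLE_ID_TOKEN),
        columns=otu_ids,
    )
    meta = pd.DataFrame(meta_rows, index=table.index)
    return table, meta, truth


def simulate_tree(otu_ids: list[str], seed: int = 0) -> "TreeNode":
    """Random rooted binary tree over ``otu_ids`` with positive branch lengths.

    Built by coalescent-style random pairwise joins; branch lengths are
    exponential(1) draws offset away from zero.  Returns a
    :class:`skbio.TreeNode`.
    """
    from skbio import TreeNode

    if len(otu_ids) < 2:
        raise ValueError(f"need at least 2 OTU ids, got {len(otu_ids)}")
    if len(set(otu_ids)) != len(otu_ids):
        raise ValueError("OTU ids must be unique")
    rng = np.random.default_rng(seed)

    nodes = [TreeNode(name=str(o)) for o in otu_ids]
    for node in nodes:
        node.length = round(float(0.05 + rng.exponential(1.0)), 6)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        parent.length = round(float(0.05 + rng.exponential(1.0)), 6)
        parent.extend([nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def simulate_taxonomy(
    otu_ids: list[str],
    phyla_weights: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each OTU a full synthetic lineage, phyla drawn per ``phyla_weights``.

    Lower ranks are synthetic labels nested under the phylum (``<Phylum>_faM``
    etc.) so family-level aggregation behaves like a real taxonomy.
    """
    if not otu_ids:
        raise ValueError("otu_ids must be non-empty")
    weights = dict(phyla_weights or DEFAULT_PHYLA_WEIGHTS)
    if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
        raise ValueError("phyla weights must be nonnegative and not all zero")
    rng = np.random.default_rng(seed)
    phyla = list(weights)
    p = np.asarray([weights[k] for k in phyla], dtype=float)
    p /= p.sum()
    draws = rng.choice(len(phyla), size=len(otu_ids), p=p)
    records = []
    for otu, d in zip(otu_ids, draws):
        phylum = phyla[d]
        cls = f"{phylum}_c{rng.integers(1, 3)}"
        order = f"{cls}_o{rng.integers(1, 3)}"
        family = f"{order}_f{rng.integers(1, 4)}"
        genus = f"{family}_g{rng.integers(1, 5)}"
        records.append(
            {
                "otu_id": otu,
                "phylum": phylum,
                "class": cls,
                "order": order,
                "family": family,
                "genus": genus,
                "nearest_named_species": f"{genus}_sp",
            }
        )
    return pd.DataFrame(records).set_index("otu_id")
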