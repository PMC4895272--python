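"""Synthetic matched expression data with planted regulatory modules.

Each planted module is a rank-1 signal: one latent factor per sample,
shared by the module's member miRNAs (loading +m) and member mRNAs
(loading -m for the ``anti`` sign pattern, reflecting miRNA repression;
``mixed`` assigns each mRNA a random sign to exercise absolute-value
weighting). Every feature additionally receives i.i.d. Gaussian noise;
non-members are pure noise. Ground-truth memberships are returned so that
every pipeline stage can be tested against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ScenarioError
from .io import ExpressionMatrix, InteractionReference, MatchedPair


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: member counts, latent-factor loading, sign pattern."""

    n_mirnas: int
    n_mrnas: int
    loading: float = 1.0
    sign_pattern: str = "anti"

    def __post_init__(self) -> None:
        if self.n_mirnas < 1 or self.n_mrnas < 1:
            raise ScenarioError("module member counts must be positive")
        if self.loading < 0:
            raise ScenarioError("loading magnitude must be >= 0")
        if self.sign_pattern not in ("anti", "mixed"):
            raise ScenarioError("sign_pattern must be 'anti' or 'mixed'")


@dataclass(frozen=True)
class PlantedModule:
    """Ground-truth membership of one planted module."""

    mirna_ids: frozenset[str]
    mrna_ids: frozenset[str]

    @property
    def all_ids(self) -> frozenset[str]:
        return self.mirna_ids | self.mrna_ids


@dataclass
class PlantedScenario:
    """Generator settings for matched matrices with planted modules.

    Defaults define the study condition used throughout testing: 60 samples,
    30 miRNAs x 200 mRNAs, two disjoint anti-correlated modules of
    (4 miRNAs, 20 mRNAs) and (5 miRNAs, 30 mRNAs), unit loading, noise
    standard deviation 0.5.
    """

    n_samples: int = 60
    n_mirnas: int = 30
    n_mrnas: int = 200
    modules: list[ModuleSpec] = field(
        default_factory=lambda: [ModuleSpec(4, 20), ModuleSpec(5, 30)]
    )
    noise_sd: float = 0.5
    overlap: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        self.modules = [
            m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in self.modules
        ]
        if self.n_samples < 3:
            raise ScenarioError("need at least 3 samples")
        if self.noise_sd <= 0:
            raise ScenarioError("noise_sd must be > 0")
        if not 0.0 <= self.overlap < 1.0:
            raise ScenarioError("overlap fraction must lie in [0, 1)")
        need_mi = self._assign_counts([m.n_mirnas for m in self.modules])
        need_mr = self._assign_counts([m.n_mrnas for m in self.modules])
        if need_mi > self.n_mirnas or need_mr > self.n_mrnas:
            raise ScenarioError(
                f"modules need {need_mi} miRNAs and {need_mr} mRNAs but only "
                f"{self.n_mirnas}/{self.n_mrnas} are available"
            )

    def _assign_counts(self, sizes: list[int]) -> int:
        """Distinct features needed when consecutive modules share `overlap`."""
        total = 0
        for i, s in enumerate(sizes):
            shared = int(self.overlap * s) if i > 0 else 0
            total += s - shared
        return total


def _assign_members(sizes: list[int], overlap: float, prefix: str,
                    fmt: str) -> list[list[str]]:
    """Contiguous blocks of IDs; module i >= 1 reuses the tail of module i-1."""
    blocks: list[list[str]] = []
    cursor = 0
    for i, s in enumerate(sizes):
        shared = int(overlap * s) if i > 0 else 0
        start = cursor - shared
        blocks.append([fmt.format(prefix=prefix, k=k) for k in range(start, start + s)])
        cursor = start + s
    return blocks


def generate(scenario: PlantedScenario) -> tuple[MatchedPair, list[PlantedModule]]:
    """Generate a matched expression pair and the planted ground truth.

    Deterministic given the scenario seed: the same scenario yields
    bit-identical matrices.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_samples
    mirna_ids = [f"miR-{i:03d}" for i in range(scenario.n_mirnas)]
    mrna_ids = [f"gene-{j:04d}" for j in range(scenario.n_mrnas)]

    mi_blocks = _assign_members([m.n_mirnas for m in scenario.modules],
                                scenario.overlap, "miR", "{prefix}-{k:03d}")
    mr_blocks = _assign_members([m.n_mrnas for m in scenario.modules],
                                scenario.overlap, "gene", "{prefix}-{k:04d}")

    X = rng.normal(0.0, scenario.noise_sd, size=(scenario.n_mirnas, n))
    Y = rng.normal(0.0, scenario.noise_sd, size=(scenario.n_mrnas, n))
    mi_pos = {f: i for i, f in enumerate(mirna_ids)}
    mr_pos = {f: j for j, f in enumerate(mrna_ids)}

    truth: list[PlantedModule] = []
    for spec, mi_members, mr_members in zip(scenario.modules, mi_blocks, mr_blocks):
        factor = rng.normal(0.0, 1.0, size=n)
        for f in mi_members:
            X[mi_pos[f]] += spec.loading * factor
        if spec.sign_pattern == "anti":
            signs = -np.ones(len(mr_members))
        else:
            signs = rng.choice([-1.0, 1.0], size=len(mr_members))
        for sgn, f in zip(signs, mr_members):
            Y[mr_pos[f]] += sgn * spec.loading * factor
        truth.append(PlantedModule(frozenset(mi_members), frozenset(mr_members)))

    sample_ids = [f"s{t:03d}" for t in range(n)]
    pair = MatchedPair(
        mirna=ExpressionMatrix(mirna_ids, sample_ids, X),
        mrna=ExpressionMatrix(mrna_ids, sample_ids, Y),
    )
    return pair, truth


def reference_from_truth(truth: list[PlantedModule]) -> InteractionReference:
    """All within-module miRNA x mRNA cross pairs as 'confirmed' interactions."""
    pairs = set()
    for mod in truth:
        for m in mod.mirna_ids:
            for g in mod.mrna_ids:
                pairs.add((m, g))
    return InteractionReference(pairs=frozenset(pairs))


def truth_to_json(truth: list[PlantedModule]) -> list[dict]:
    return [
        {"mirnas": sorted(m.mirna_ids), "mrnas": sorted(m.mrna_ids)} for m in truth
    ]
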