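"""Run-wide configuration.

All tunable constants of the benchmark live here with their production
defaults: LDDT thresholds and inclusion radius, the binding-site radius for
symmetry-corrected ligand RMSD, clustering identities (99% for proteins,
100% for peptides and nucleic acids), the easy/medium template rules
(85% identity, 70% coverage, <45 uncovered residues on targets longer than
250 residues, e-value <= 1e-4), ligand-pose success thresholds (1/2/5 A,
success strictly below 2 A), and the reference-eligibility caps
(EM resolution <= 4.0 A, <= 200 polymer chains, <= 100 copies of one entity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class LDDTParams:
    """Parameters of the local distance difference test.

    inclusion_radius
        Reference inter-atomic distances are collected up to this radius (A).
    thresholds
        Distance-error tolerances (A); the per-distance score is the fraction
        of thresholds the model error stays within.
    stereo_check
        Remove model atoms with grossly non-physical geometry (bond lengths
        off by more than ``bond_tolerance_sigmas`` standard deviations, or
        non-bonded contacts below ``clash_distance``) before scoring.
    """

    inclusion_radius: float = 15.0
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    stereo_check: bool = True
    bond_tolerance_sigmas: float = 12.0
    clash_distance: float = 1.5

    def __post_init__(self) -> None:
        if not self.thresholds or any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be increasing")
        if self.inclusion_radius <= 0:
            raise ValueError("inclusion_radius must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Every benchmark constant, overridable in one place."""

    lddt: LDDTParams = field(default_factory=LDDTParams)

    # ligand scoring
    pli_inclusion_radius: float = 4.0     # polymer-ligand contact radius (A)
    site_radius: float = 4.0              # binding-site definition radius (A)
    automorphism_cap: int = 10_000
    success_thresholds: tuple[float, ...] = (1.0, 2.0, 5.0)
    success_threshold: float = 2.0        # headline success rule, strict "<"

    # chain mapping
    exhaustive_copy_limit: int = 6

    # sequence clustering
    protein_cluster_identity: float = 99.0
    other_cluster_identity: float = 100.0

    # template difficulty rules
    easy_identity: float = 85.0
    easy_coverage: float = 70.0
    max_uncovered: int = 45
    long_target_length: int = 250
    medium_evalue: float = 1e-4

    # reference eligibility
    em_resolution_cutoff: float = 4.0
    max_polymer_chains: int = 200
    max_copies_single_entity: int = 100

    # ligand classification
    ligand_set_exclude: frozenset[str] = frozenset({"HOH"})
    lipinski_allow_one_violation: bool = False
    drug_like_max_occurrence: int = 100

    seed: int = 0

    def with_options(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


DEFAULT_CONFIG = RunConfig()
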