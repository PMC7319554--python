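"""Run configuration shared by the library, the CLI and the map scans."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with documented defaults.

    cutoff_A      interaction cutoff of the elastic network, Å
    k             uniform spring constant, k_BT/Å² (pure unit: all reported
                  energies are ratios, so its absolute value cancels)
    n_modes       number of lowest-frequency non-rigid modes retained
    alpha         binding-spring scale: a bound site gains springs of
                  stiffness alpha*k between all its residue pairs
    theta_up      stabilizing-mutation factor applied to incident springs (>1)
    theta_down    destabilizing-mutation factor (in [0,1); >0 keeps the
                  network connected)
    probe_len     probe window length for the probing map (residues)
    mode_matching 'rank' pairs unperturbed/perturbed modes by frequency rank;
                  'overlap' pairs by maximal |eigenvector dot product|
    coupling_neighbors_only
                  True: the elastic-work coupling sums over network
                  neighbors of each residue; False: over all residues
    site_pairs    'all': binding springs between every residue pair of the
                  site; 'within_cutoff': only pairs inside the network cutoff
    center        'global': modulation centered on the mean over all analyzed
                  residues; 'per_chain': centered within each chain
    rigid_tol     rigid-mode threshold, relative to the largest eigenvalue
    seed          seed for any stochastic step (fixture generation, nulls)
    output_dir    where CLI commands write their files
    """

    cutoff_A: float = 10.0
    k: float = 1.0
    n_modes: int = 10
    alpha: float = 1.0
    theta_up: float = 2.0
    theta_down: float = 0.01
    probe_len: int = 3
    mode_matching: str = "rank"
    coupling_neighbors_only: bool = True
    site_pairs: str = "all"
    center: str = "global"
    rigid_tol: float = 1e-9
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.theta_up <= 1:
            raise ValueError("theta_up must be > 1")
        if not 0 <= self.theta_down < 1:
            raise ValueError("theta_down must be in [0, 1)")
        if self.mode_matching not in ("rank", "overlap"):
            raise ValueError("mode_matching must be 'rank' or 'overlap'")
        if self.site_pairs not in ("all", "within_cutoff"):
            raise ValueError("site_pairs must be 'all' or 'within_cutoff'")
        if self.center not in ("global", "per_chain"):
            raise ValueError("center must be 'global' or 'per_chain'")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        d = self.to_dict()
        d.update(kwargs)
        return RunConfig.from_dict(d)
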