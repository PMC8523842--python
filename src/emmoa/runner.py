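"""End-to-end orchestration of the two-stage channel-selection run."""
from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .data import EpochSet, StimulusSpec
from .io import write_archive, write_run_manifest
from .objectives import EvaluationLedger, ObjectiveBackend
from .operators import EAConfig
from .pareto import ParetoArchive
from .stage1 import Stage1Result, run_stage1
from .stage2 import Stage2Result, VariableGroups, run_stage2


@dataclass
class RunResult:
    ps_mi: ParetoArchive
    ps_ssvep: ParetoArchive
    final_ps: ParetoArchive
    groups: VariableGroups
    ledger: EvaluationLedger
    config: EAConfig
    stage1: Stage1Result
    stage2: Stage2Result
    timings: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "software_version": __version__,
            "config": asdict(self.config),
            "ledger": self.ledger.summary(),
            "stage1_generations": self.stage1.generations,
            "stage2_candidates": self.stage2.candidates,
            "archive_sizes": {"ps_mi": len(self.ps_mi),
                              "ps_ssvep": len(self.ps_ssvep),
                              "final_ps": len(self.final_ps)},
            "variable_groups": self.groups.report(),
            "timings_seconds": self.timings,
        }


def run_emmoa(mi_epochs: EpochSet, ssvep_epochs: EpochSet, stim: StimulusSpec,
              config: Optional[EAConfig] = None,
              seed: Optional[int] = None) -> RunResult:
    """Run Stage 1 (multitasking search) then Stage 2 (variable analysis and
    local search) on the given data, under one evaluation budget.

    Stage 1 is allotted (1 - stage2_fraction) of the budget; the full
    budget then applies through Stage 2. The single `seed` (falling back to
    config.seed) drives every random draw.
    """
    config = config or EAConfig(n_channels=mi_epochs.n_channels)
    if seed is not None:
        config = EAConfig(**{**asdict(config), "seed": seed})
    rng = np.random.default_rng(config.seed)
    ledger = EvaluationLedger(budget=config.stage1_budget)
    backend = ObjectiveBackend(mi_epochs, ssvep_epochs, stim, ledger,
                               n_folds=config.cv_folds, cv_seed=config.cv_seed)
    t0 = time.perf_counter()
    s1 = run_stage1(backend, config, rng)
    t1 = time.perf_counter()
    ledger.budget = config.evaluation_budget
    s2 = run_stage2(s1.ps_mi, s1.ps_ssvep, backend, config, rng)
    t2 = time.perf_counter()
    return RunResult(
        ps_mi=s1.ps_mi, ps_ssvep=s1.ps_ssvep, final_ps=s2.final_ps,
        groups=s2.groups, ledger=ledger, config=config, stage1=s1, stage2=s2,
        timings={"stage1": round(t1 - t0, 3), "stage2": round(t2 - t1, 3)},
    )


def write_run(result: RunResult, out_dir: str | Path,
              channel_names: tuple[str, ...]) -> Path:
    """Write the three archives, the variable-group report and the run
    manifest into a run directory; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    common = {"seed": result.config.seed}
    write_archive(result.ps_mi, out_dir / "ps_mi", channel_names, common)
    write_archive(result.ps_ssvep, out_dir / "ps_ssvep", channel_names, common)
    write_archive(result.final_ps, out_dir / "final_ps", channel_names, common)
    return write_run_manifest(out_dir / "manifest.json", result.manifest())
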