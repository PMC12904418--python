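"""Parameter-recovery experiments on synthetic studies.

One study at the published scale (68 participants, 14 days) is simulated
from the generative mirror with the study's reported standardized
coefficients as generating values and trait variances calibrated to the
reported between-person stabilities; the DSEM is then fit exactly as it
would be on real data (multiple imputation, 2 chains, 5,000 iterations)
and the pooled posterior means are compared against the generating
coefficients. All randomness derives from one base seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .dsem import FitResult, ModelSpec, fit
from .panel import filter_missing, impute
from .synth import SynthConfig, calibrate_between, simulate_panel


@dataclass
class RecoveryResult:
    config: SynthConfig
    panel: pd.DataFrame
    result: FitResult

    def beta(self, predictor: str, outcome: str, level: str = "within") -> float:
        return self.result.get_path(predictor, outcome, level).beta


def _run(cfg: SynthConfig, spec: ModelSpec, seed: int, m: int,
         calibrate_n: int, max_missing_days: int = 7) -> RecoveryResult:
    cfg = calibrate_between(cfg, n_check=calibrate_n, seed=seed + 11)
    panel, _ = simulate_panel(cfg, seed=seed + 13)
    panel, _ = filter_missing(panel, max_missing_days=max_missing_days,
                              n_days=cfg.n_days)
    imps = impute(panel, m=m, seed=seed + 17, variables=cfg.variables)
    result = fit(spec, imps)
    return RecoveryResult(config=cfg, panel=panel, result=result)


def model1_recovery(seed: int = 0, n_participants: int = 68, n_days: int = 14,
                    chains: int = 2, iterations: int = 5000, m: int = 5,
                    calibrate_n: int = 3000) -> RecoveryResult:
    """Three-variable recovery study (TSU, SUiB, total sleep)."""
    cfg = replace(SynthConfig.model1(), n_participants=n_participants,
                  n_days=n_days)
    spec = ModelSpec.model1(chains=chains, iterations=iterations,
                            seed=seed + 19)
    return _run(cfg, spec, seed, m, calibrate_n)


def model2_recovery(seed: int = 0, n_participants: int = 68, n_days: int = 14,
                    chains: int = 2, iterations: int = 5000, m: int = 5,
                    calibrate_n: int = 3000) -> RecoveryResult:
    """Five-variable recovery study (TSU, SUiB and the three sleep stages)."""
    cfg = replace(SynthConfig.model2(), n_participants=n_participants,
                  n_days=n_days)
    spec = ModelSpec.model2(chains=chains, iterations=iterations,
                            seed=seed + 23)
    return _run(cfg, spec, seed, m, calibrate_n)
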