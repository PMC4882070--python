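"""Shared helpers for the numbered analysis drivers.

The default study (population cohort of 18,715, 53 ascertained families,
212-SNP panel) is simulated deterministically from STUDY_SEED and cached
under scratch/ so the drivers can be run independently without re-paying
the simulation cost.
"""

import pickle
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY_SEED = 1


def get_study(seed: int = STUDY_SEED):
    from famlipid.config import SimulationConfig
    from famlipid.simulate import simulate_study

    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"study_seed{seed}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    study = simulate_study(SimulationConfig(seed=seed))
    with open(cache, "wb") as fh:
        pickle.dump(study, fh)
    return study


def get_scores(study):
    """Fit population weights, score everyone, flag high scores and
    Mendelian carriers.  Returns (flags frame, population scores)."""
    import pandas as pd

    import famlipid as fl

    w_ldl = fl.estimate_weights(study.pop_genotypes, study.pop_phenotypes, "LDL", study.panel)
    w_tg = fl.estimate_weights(study.pop_genotypes, study.pop_phenotypes, "TG", study.panel)
    fam = pd.DataFrame(dict(
        score_LDL=fl.compute_scores(study.fam_genotypes, w_ldl, study.panel),
        score_TG=fl.compute_scores(study.fam_genotypes, w_tg, study.panel)))
    pop = pd.DataFrame(dict(
        score_LDL=fl.compute_scores(study.pop_genotypes, w_ldl, study.panel),
        score_TG=fl.compute_scores(study.pop_genotypes, w_tg, study.panel)))
    carriers = fl.flag_mendelian_carriers(
        study.fam_genotypes, fl.call_apoe(study.fam_genotypes)
    ).set_index("individual_id")["carrier"]
    flags = fl.flag_high_scores(fam, pop, carriers)
    return flags, pop


def save(df, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False)
    print(f"  wrote {path.relative_to(ROOT)}")
    return path


if __name__ == "__main__":
    sys.exit("import this module from the numbered drivers")
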