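"""Deterministic fixture generation: everything the suite needs, no downloads.

Three kinds: a random peptide FASTA, a planted-landscape spec with certified
optimum, and a paired-variant suite of configs sharing seeds for the
three-way comparison.  The same seed always produces byte-identical files.
"""
from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from .landscapes import PlantedLandscape, planted_landscape

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

FIXTURE_KINDS = ("random_peptide", "planted", "compare_suite")


def random_peptide(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))


def landscape_spec(ls: PlantedLandscape) -> Dict:
    """Self-contained, reloadable description of a planted landscape."""
    return {
        "m": int(ls.m),
        "sigma_star": [round(float(x), 10) for x in ls.sigma_star],
        "depth": float(ls.depth),
        "trap_coords": [int(i) for i in ls.trap_coords],
        "trap_shifts_deg": [round(float(s), 10) for s in ls.trap_shifts_deg],
        "trap_depth_frac": float(ls.trap_depth_frac),
        "trap_sharpness": int(ls.trap_sharpness),
        "certified_minimum": 0.0,
    }


def landscape_from_spec(spec: Dict) -> PlantedLandscape:
    spec = dict(spec)
    spec.pop("certified_minimum", None)
    return PlantedLandscape(
        m=spec["m"],
        sigma_star=np.array(spec["sigma_star"], dtype=float),
        depth=spec["depth"],
        trap_coords=np.array(spec["trap_coords"], dtype=int),
        trap_shifts_deg=np.array(spec["trap_shifts_deg"], dtype=float),
        trap_depth_frac=spec["trap_depth_frac"],
        trap_sharpness=spec["trap_sharpness"],
    )


def generate_fixture(kind: str, spec: Optional[Dict], seed: int, out_dir) -> List[Path]:
    """Write fixture files of the requested kind; returns the paths written."""
    spec = dict(spec or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "random_peptide":
        length = int(spec.get("length", 5))
        seq = random_peptide(length, seed)
        path = out / f"peptide_len{length}_seed{seed}.fasta"
        path.write_text(f">random_peptide_len{length}_seed{seed}\n{seq}\n")
        return [path]
    if kind == "planted":
        ls = planted_landscape(
            m=int(spec.get("m", 19)),
            n_traps=int(spec.get("n_traps", 5)),
            depth=float(spec.get("depth", 1.0)),
            rng=np.random.default_rng(seed),
        )
        path = out / f"planted_m{ls.m}_seed{seed}.yaml"
        path.write_text(yaml.safe_dump(landscape_spec(ls), sort_keys=False))
        return [path]
    if kind == "compare_suite":
        # paired, loadable run configs for the three variants at shared seeds
        n_seeds = int(spec.get("n_seeds", 10))
        paths = []
        for variant in ("cmqa", "mqa_dep", "csa"):
            for run_seed in range(seed, seed + n_seeds):
                cfg = {
                    "variant": variant,
                    "seed": run_seed,
                    "instance": {
                        "kind": "planted",
                        "m": int(spec.get("m", 19)),
                        "n_traps": int(spec.get("n_traps", 5)),
                        "landscape_seed": seed,
                    },
                }
                p = out / f"suite_{variant}_seed{run_seed}.yaml"
                p.write_text(yaml.safe_dump(cfg, sort_keys=False))
                paths.append(p)
        return paths
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
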