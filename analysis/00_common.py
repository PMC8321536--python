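"""Shared plumbing for the numbered analysis drivers.

Builds (or reloads from scratch/) the synthetic study system that all
drivers analyze, so each script can be run on its own. Large intermediates
live under scratch/; the drivers write small result tables under results/.
"""

from __future__ import annotations

import argparse
import os
import pickle
import sys

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
sys.path.insert(0, os.path.join(ROOT, "src"))

RESULTS = os.path.join(ROOT, "results")
SCRATCH = os.path.join(ROOT, "scratch")

DEFAULT_SEED = 1


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    ap.add_argument("--rebuild", action="store_true",
                    help="ignore any cached study system")
    return ap.parse_args()


def get_system(seed: int, rebuild: bool = False):
    """Build the study system once per seed; cache it under scratch/."""
    from codonpref.pipeline import build_study_system

    os.makedirs(SCRATCH, exist_ok=True)
    cache = os.path.join(SCRATCH, f"study_system_seed{seed}.pkl")
    if not rebuild and os.path.exists(cache):
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    system = build_study_system(seed)
    with open(cache, "wb") as fh:
        pickle.dump(system, fh)
    return system


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)
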