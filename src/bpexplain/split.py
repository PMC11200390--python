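"""Patient-stratified train/validation/test splitting with class minima.

Slices of one patient are correlated, so all slices of a patient must land
in the same set ("patient-stratified").  The target fractions are 62% train,
19% validation, 19% test of *slices*, and every BPE class must make up at
least ``min_fraction`` (default 10%) of each set's slices; the 5-fold
cross-validation splits of the non-test portion relax the minimum to
``cv_min_fraction`` (default 2%).

Constraints are satisfied by rejection sampling: random patient
permutations are packed greedily toward the target fractions and the
candidate is accepted only if all constraints hold.  Infeasibility raises
an explicit error naming the tightest violated constraint — constraints are
never silently relaxed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .tables import FeatureTable

SET_NAMES = ("train", "val", "test")
DEFAULT_FRACTIONS = {"train": 0.62, "val": 0.19, "test": 0.19}


class SplitInfeasibleError(RuntimeError):
    """No assignment satisfying the constraints was found within max_attempts."""


@dataclasses.dataclass
class SplitAssignment:
    """Mapping slice_id -> set name, plus optional CV fold patient partitions."""

    assignment: dict[str, str]
    cv_folds: list[dict[str, list[str]]] | None = None  # [{"train": [...], "val": [...]}]

    def slice_ids(self, set_name: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == set_name]

    def mask(self, table: FeatureTable, set_name: str) -> np.ndarray:
        return np.array([self.assignment[s] == set_name for s in table.slice_id])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"assignment": self.assignment, "cv_folds": self.cv_folds}, indent=2
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitAssignment":
        d = json.loads(Path(path).read_text())
        return cls(d["assignment"], d.get("cv_folds"))


def _patient_info(table: FeatureTable):
    patients = np.array(sorted(set(table.patient_id)), dtype=object)
    n_slices = {p: 0 for p in patients}
    p_label = {}
    for p, lab in zip(table.patient_id, table.label):
        n_slices[p] += 1
        p_label[p] = int(lab)
    return patients, n_slices, p_label


def _class_fraction_check(
    table: FeatureTable, members: dict[str, list], min_fraction: float
) -> tuple[bool, str]:
    """Check per-set class minima; return (ok, tightest-violation message)."""
    label_of = dict(zip(table.slice_id, table.label))
    patient_slices: dict = {}
    for s, p in zip(table.slice_id, table.patient_id):
        patient_slices.setdefault(p, []).append(s)
    worst: tuple[float, str] | None = None
    for set_name, pats in members.items():
        labels = [label_of[s] for p in pats for s in patient_slices[p]]
        total = len(labels)
        if total == 0:
            return False, f"set {set_name!r} received no slices"
        counts = np.bincount(labels, minlength=5)[1:5]
        for c in range(4):
            frac = counts[c] / total
            if frac < min_fraction:
                margin = min_fraction - frac
                msg = (
                    f"class {c + 1} holds {frac:.1%} of {set_name!r} slices, "
                    f"below the required minimum {min_fraction:.0%}"
                )
                if worst is None or margin > worst[0]:
                    worst = (margin, msg)
    if worst is not None:
        return False, worst[1]
    return True, ""


def stratified_split(
    table: FeatureTable,
    fractions: dict[str, float] | None = None,
    min_fraction: float = 0.10,
    tolerance: float = 0.05,
    seed: int | None = None,
    max_attempts: int = 10_000,
) -> SplitAssignment:
    """Patient-stratified random split into train/val/test.

    Greedy packing: walk a random patient permutation and assign each
    patient to the set currently furthest below its target slice count
    (ties broken in the fixed order train, val, test).  Accept the candidate
    only if slice fractions are within ``tolerance`` of the targets and
    every class reaches ``min_fraction`` in every set.
    """
    fractions = dict(DEFAULT_FRACTIONS if fractions is None else fractions)
    if set(fractions) != set(SET_NAMES):
        raise ValueError(f"fractions must have keys {SET_NAMES}")
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")

    patients, n_slices, _ = _patient_info(table)
    if len(patients) < 3:
        raise ValueError("need at least 3 patients to form three sets")
    present = set(table.label.tolist())
    if present != {1, 2, 3, 4}:
        raise ValueError(f"all 4 classes must be present, got {sorted(present)}")

    total = table.n_slices
    rng = np.random.default_rng(seed)
    last_violation = "no attempt made"
    for _ in range(max_attempts):
        perm = rng.permutation(patients)
        assigned: dict[str, int] = {s: 0 for s in SET_NAMES}
        members: dict[str, list] = {s: [] for s in SET_NAMES}
        for p in perm:
            deficits = {
                s: fractions[s] * total - assigned[s] for s in SET_NAMES
            }
            target = max(SET_NAMES, key=lambda s: deficits[s])
            members[target].append(p)
            assigned[target] += n_slices[p]

        frac_ok = True
        for s in SET_NAMES:
            frac = assigned[s] / total
            if abs(frac - fractions[s]) > tolerance:
                frac_ok = False
                last_violation = (
                    f"set {s!r} holds {frac:.1%} of slices, outside "
                    f"{fractions[s]:.0%} +/- {tolerance:.0%}"
                )
                break
        if not frac_ok:
            continue
        ok, msg = _class_fraction_check(table, members, min_fraction)
        if not ok:
            last_violation = msg
            continue

        assignment = {}
        for set_name, pats in members.items():
            pset = set(pats)
            for s, p in zip(table.slice_id, table.patient_id):
                if p in pset:
                    assignment[s] = set_name
        # preserve table row order in the mapping
        assignment = {s: assignment[s] for s in table.slice_id}
        return SplitAssignment(assignment)

    raise SplitInfeasibleError(
        f"no valid split in {max_attempts} attempts; tightest violated "
        f"constraint: {last_violation}"
    )


def make_cv_folds(
    table: FeatureTable,
    assignment: SplitAssignment,
    k: int = 5,
    cv_min_fraction: float = 0.02,
    seed: int | None = None,
    max_attempts: int = 10_000,
) -> SplitAssignment:
    """Partition non-test patients into k cross-validation folds.

    Each patient appears in exactly one fold's validation set; per fold,
    every class must reach ``cv_min_fraction`` of both the fold-train and
    fold-validation slices.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    test_patients = {
        p
        for p, s in zip(table.patient_id, table.slice_id)
        if assignment.assignment[s] == "test"
    }
    pool = np.array(
        sorted({p for p in table.patient_id if p not in test_patients}), dtype=object
    )
    if len(pool) < k:
        raise SplitInfeasibleError(f"only {len(pool)} non-test patients for {k} folds")

    rng = np.random.default_rng(seed)
    last_violation = "no attempt made"
    for _ in range(max_attempts):
        perm = rng.permutation(pool)
        fold_patients = [list(chunk) for chunk in np.array_split(perm, k)]
        folds = []
        ok = True
        for i in range(k):
            val = fold_patients[i]
            train = [p for j in range(k) if j != i for p in fold_patients[j]]
            good, msg = _class_fraction_check(
                table, {"cv-train": train, "cv-val": val}, cv_min_fraction
            )
            if not good:
                ok = False
                last_violation = f"fold {i}: {msg}"
                break
            folds.append(
                {"train": [str(p) for p in train], "val": [str(p) for p in val]}
            )
        if ok:
            return SplitAssignment(dict(assignment.assignment), folds)

    raise SplitInfeasibleError(
        f"no valid {k}-fold partition in {max_attempts} attempts; tightest "
        f"violated constraint: {last_violation}"
    )
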