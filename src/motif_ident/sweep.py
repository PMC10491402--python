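"""Batch assessment of (motif, case, measurement-combo) instances.

One *instance* is a model structure together with a measurement
combination.  The library spans 2352 basic + 1296 antithetic = 3648
instances.  This module runs assessments over arbitrary slices of that
space, streams the per-instance records to CSV (resumably), classifies
measurement patterns as always sufficient / always insufficient / case-
and-motif dependent, and aggregates identifiability scores

    score = (# identifiable instances) / (# instances analyzed)

by case, by motif, by controller type, and for the basic-versus-antithetic
comparison of kinetically comparable cases.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from .motifs import (
    ANTITHETIC_CASES,
    BASIC_CASES,
    InvalidSelectionError,
    Model,
    build_model,
)
from .outputs import MeasurementCombo, build_output_model, enumerate_combos, name_for
from .oi import DEFAULT_DRAWS, DEFAULT_SYMBOLIC_CEILING, assess

__all__ = [
    "SweepRecord",
    "CATEGORIES",
    "combo_category",
    "combo_pattern",
    "iter_instances",
    "count_instances",
    "run_sweep",
    "identifiability_score",
    "classify_combos",
    "cross_species_subset",
    "aggregate_tables",
    "records_to_csv",
    "records_from_csv",
]

CATEGORIES = ("always_insufficient", "always_sufficient", "case_and_motif_dependent")

_CONTROLLER_SPECIES = {"E", "E1", "E2"}

# token -> related species, per family (fixed by which balance equation the
# measured quantity enters)
_RELATION = {
    "basic": {
        "A": {"A"}, "di": {"A"}, "do": {"A"}, "jc": {"A"},
        "E": {"E"}, "js": {"E"}, "jd": {"E"},
    },
    "antithetic": {
        "A": {"A"}, "di": {"A"}, "do": {"A"}, "jc": {"A"},
        "E1": {"E1"}, "js1": {"E1"}, "E2": {"E2"}, "js2": {"E2"},
        "ja": {"E1", "E2"},
    },
}

_CONC_TOKENS = {"A", "E", "E1", "E2"}


def _relations(family: str, tokens: Sequence[str]) -> list:
    table = _RELATION[family]
    try:
        return [frozenset(table[t]) for t in tokens]
    except KeyError as exc:
        raise InvalidSelectionError(f"unknown measurement token {exc} for {family}") from exc


def combo_pattern(family: str, tokens: Sequence[str]) -> str:
    """Species-relation pattern of a measurement combination.

    Patterns are keyed on measurement kind (concentration/flow) and on the
    species each measurement relates to — never on literal flow names — so
    they transfer across motifs and cases.
    """
    tokens = tuple(tokens)
    rels = _relations(family, tokens)
    kinds = ["conc" if t in _CONC_TOKENS else "flow" for t in tokens]
    if len(tokens) == 1:
        return f"one {'concentration' if kinds[0] == 'conc' else 'flow'}"
    union = rels[0] | rels[1]
    if union <= _CONTROLLER_SPECIES and family == "antithetic":
        return "two measurements, controller species only"
    if kinds[0] == kinds[1] == "conc":
        return "two concentrations"
    same = rels[0] == rels[1]
    if "conc" in kinds:
        return f"concentration and flow, {'same' if same else 'different'} species"
    return f"two flows, {'same' if same else 'different'} species"


def combo_category(family: str, tokens: Sequence[str]) -> str:
    """Structural classification of a measurement combination.

    Always insufficient: any single measurement; any pair related to the
    same species; (antithetic) any pair related only to the controller
    species.  Always sufficient: both concentrations (basic); concentration
    of A, or the outflow disturbance d_o, paired with any controller-related
    measurement (antithetic).  Everything else is case and motif dependent.
    """
    tokens = tuple(tokens)
    rels = _relations(family, tokens)
    if len(tokens) == 1:
        return "always_insufficient"
    a_related = [r == frozenset({"A"}) for r in rels]
    if all(a_related):
        return "always_insufficient"
    if not any(a_related):
        # same controller species, or (antithetic) spread over E1/E2 only
        return "always_insufficient"
    if family == "basic":
        if set(tokens) == {"A", "E"}:
            return "always_sufficient"
        return "case_and_motif_dependent"
    # antithetic: one A-related and one controller-related member
    if "A" in tokens or "do" in tokens:
        return "always_sufficient"
    return "case_and_motif_dependent"


# ---------------------------------------------------------------------------
# instance enumeration
# ---------------------------------------------------------------------------


def iter_instances(
    families: Optional[Sequence[str]] = None,
    motifs: Optional[Sequence[int]] = None,
    cases: Optional[Sequence[str]] = None,
    combos: Optional[Sequence] = None,
    categories: Optional[Sequence[str]] = None,
):
    """Yield (model, combo) pairs for a filtered slice of the library."""
    families = tuple(families) if families else ("basic", "antithetic")
    motifs = tuple(motifs) if motifs else tuple(range(1, 9))
    wanted_combos = None
    if combos is not None:
        wanted_combos = {tuple(sorted(name_for(t) for t in c)) for c in combos}
    for family in families:
        case_table = BASIC_CASES if family == "basic" else ANTITHETIC_CASES
        family_cases = [c for c in case_table if cases is None or c in cases]
        for index in motifs:
            for case_id in family_cases:
                model = build_model(family, index, case_id)
                for combo in enumerate_combos(model):
                    if wanted_combos is not None and \
                            tuple(sorted(combo.members)) not in wanted_combos:
                        continue
                    if categories is not None and \
                            combo_category(family, combo.tokens) not in categories:
                        continue
                    yield model, combo


def count_instances(**filters) -> int:
    return sum(1 for _ in iter_instances(**filters))


# ---------------------------------------------------------------------------
# sweep records
# ---------------------------------------------------------------------------

CSV_COLUMNS = (
    "family", "motif", "case", "method", "mode", "measurements",
    "n", "q", "N", "rank", "identifiable", "k_used", "stop_condition", "seed",
)


@dataclass(frozen=True)
class SweepRecord:
    """One assessed instance: a row of the results tables."""

    family: str
    motif: int
    case_id: str
    combo: tuple            # measurement tokens
    method: int
    mode: str
    n: int
    q: int
    N: int
    rank: int
    identifiable: bool
    k_used: int
    stop_condition: str
    seed: int

    @property
    def key(self) -> tuple:
        return (self.family, self.motif, self.case_id, ",".join(self.combo), self.method)

    @property
    def pattern(self) -> str:
        return combo_pattern(self.family, self.combo)

    @property
    def category(self) -> str:
        return combo_category(self.family, self.combo)

    def to_row(self) -> dict:
        return {
            "family": self.family, "motif": self.motif, "case": self.case_id,
            "method": self.method, "mode": self.mode,
            "measurements": ",".join(self.combo),
            "n": self.n, "q": self.q, "N": self.N, "rank": self.rank,
            "identifiable": int(self.identifiable), "k_used": self.k_used,
            "stop_condition": self.stop_condition, "seed": self.seed,
        }

    @classmethod
    def from_row(cls, row: dict) -> "SweepRecord":
        return cls(
            family=row["family"], motif=int(row["motif"]), case_id=row["case"],
            combo=tuple(row["measurements"].split(",")),
            method=int(row["method"]), mode=row["mode"],
            n=int(row["n"]), q=int(row["q"]), N=int(row["N"]),
            rank=int(row["rank"]), identifiable=bool(int(row["identifiable"])),
            k_used=int(row["k_used"]), stop_condition=row["stop_condition"],
            seed=int(row["seed"]),
        )


def _instance_seed(base_seed: int, model: Model, combo: MeasurementCombo, method: int) -> int:
    key = f"{base_seed}|{model.name}|{combo}|{method}"
    return zlib.crc32(key.encode()) % (2**31)


def run_sweep(
    families: Optional[Sequence[str]] = None,
    motifs: Optional[Sequence[int]] = None,
    cases: Optional[Sequence[str]] = None,
    combos: Optional[Sequence] = None,
    categories: Optional[Sequence[str]] = None,
    methods: Sequence[int] = (2,),
    mode: str = "auto",
    seed: int = 0,
    draws: int = DEFAULT_DRAWS,
    low: float = 0.5,
    high: float = 1.5,
    symbolic_ceiling: int = DEFAULT_SYMBOLIC_CEILING,
    csv_path: Optional[str] = None,
    resume: bool = True,
    header_comment: Optional[str] = None,
    progress: Optional[Callable[[SweepRecord], None]] = None,
) -> list:
    """Assess every instance in the requested scope.

    Deterministic for a given ``seed`` (each instance derives its own
    sub-seed from the instance key).  When ``csv_path`` is given, records
    are appended to the file as they complete and, with ``resume``, rows
    already present are not recomputed.
    """
    done: dict = {}
    writer = None
    handle = None
    if csv_path is not None:
        path = Path(csv_path)
        if resume and path.exists():
            for rec in records_from_csv(path):
                done[rec.key] = rec
        new_file = not path.exists() or not done
        handle = open(path, "a" if (path.exists() and done) else "w", newline="")
        writer = csv.DictWriter(handle, fieldnames=CSV_COLUMNS)
        if new_file:
            if header_comment:
                for line in header_comment.splitlines():
                    handle.write(f"# {line}\n")
            writer.writeheader()

    records = []
    try:
        for model, combo in iter_instances(families=families, motifs=motifs,
                                           cases=cases, combos=combos,
                                           categories=categories):
            for method in methods:
                key = (model.family, model.index, model.case_id,
                       ",".join(combo.tokens), method)
                if key in done:
                    records.append(done[key])
                    continue
                iseed = _instance_seed(seed, model, combo, method)
                try:
                    om = build_output_model(model, combo, method=method)
                    res = assess(om, mode=mode, draws=draws, low=low, high=high,
                                 seed=iseed, symbolic_ceiling=symbolic_ceiling)
                    rec = SweepRecord(
                        family=model.family, motif=model.index,
                        case_id=model.case_id, combo=combo.tokens,
                        method=method, mode=res.mode,
                        n=model.n, q=model.q, N=model.N,
                        rank=res.rank, identifiable=res.identifiable,
                        k_used=res.k_used, stop_condition=res.stop_condition,
                        seed=iseed,
                    )
                except (ValueError, ArithmeticError) as exc:  # record and continue
                    rec = SweepRecord(
                        family=model.family, motif=model.index,
                        case_id=model.case_id, combo=combo.tokens,
                        method=method, mode=mode,
                        n=model.n, q=model.q, N=model.N,
                        rank=-1, identifiable=False, k_used=-1,
                        stop_condition=f"error:{type(exc).__name__}", seed=iseed,
                    )
                records.append(rec)
                if writer is not None:
                    writer.writerow(rec.to_row())
                    handle.flush()
                if progress is not None:
                    progress(rec)
    finally:
        if handle is not None:
            handle.close()
    return records


def records_to_csv(records: Iterable[SweepRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for rec in records:
            writer.writerow(rec.to_row())


def records_from_csv(path) -> list:
    with open(path, newline="") as fh:
        rows = csv.DictReader(line for line in fh if not line.startswith("#"))
        return [SweepRecord.from_row(row) for row in rows]


# ---------------------------------------------------------------------------
# scores, classification, aggregation
# ---------------------------------------------------------------------------


def identifiability_score(records: Sequence[SweepRecord]) -> float:
    """Fraction of identifiable instances among the supplied records."""
    records = list(records)
    if not records:
        raise ValueError("identifiability score of an empty record set is undefined")
    return sum(r.identifiable for r in records) / len(records)


def classify_combos(records: Sequence[SweepRecord]) -> dict:
    """Empirical classification of measurement patterns over a scope.

    A pattern whose instances are all identifiable is always sufficient;
    one with none identifiable is always insufficient; mixed outcomes are
    case and motif dependent.
    """
    by_pattern: dict = {}
    for rec in records:
        by_pattern.setdefault(rec.pattern, []).append(rec.identifiable)
    out = {}
    for pattern, flags in by_pattern.items():
        if all(flags):
            out[pattern] = "always_sufficient"
        elif not any(flags):
            out[pattern] = "always_insufficient"
        else:
            out[pattern] = "case_and_motif_dependent"
    return out


def cross_species_subset(records: Sequence[SweepRecord]) -> list:
    """Two-measurement instances pairing an A-related measurement with a
    controller-species-related one (the necessary condition for
    identifiability found across the library)."""
    out = []
    for rec in records:
        if len(rec.combo) != 2:
            continue
        rels = _relations(rec.family, rec.combo)
        a_related = [r == frozenset({"A"}) for r in rels]
        if any(a_related) and not all(a_related):
            out.append(rec)
    return out


def _score_entry(records: list) -> dict:
    score = identifiability_score(records)
    per_motif = {}
    for rec in records:
        per_motif.setdefault(rec.motif, []).append(rec.identifiable)
    motif_scores = {m: sum(v) / len(v) for m, v in sorted(per_motif.items())}
    return {
        "score": round(score, 2),
        "raw": score,
        "identifiable": sum(r.identifiable for r in records),
        "n_instances": len(records),
        "motif_mean": round(sum(motif_scores.values()) / len(motif_scores), 2),
        "per_motif": motif_scores,
    }


def aggregate_tables(records: Sequence[SweepRecord]) -> dict:
    """Aggregate identifiability scores.

    ``by_case`` and ``by_motif`` are restricted to the case-and-motif-
    dependent measurement combinations (the always-sufficient and
    always-insufficient patterns carry no case/motif information); the
    basic-versus-antithetic comparison drops only the always-insufficient
    combinations and is restricted to the kinetically comparable cases
    (first-order controller degradation: B2/B5/B8/B11 versus A1-A4).
    """
    records = list(records)
    dep = [r for r in records if r.category == "case_and_motif_dependent"]

    by_case: dict = {}
    for rec in dep:
        by_case.setdefault((rec.family, rec.case_id), []).append(rec)
    table_case = {f"{fam}:{case}": _score_entry(v)
                  for (fam, case), v in sorted(by_case.items())}

    by_motif: dict = {}
    for rec in dep:
        one = rec.case_id in ("B1", "B2", "B3", "B4", "B5", "B6", "A1", "A2")
        by_motif.setdefault((rec.family, "one" if one else "two", rec.motif), []).append(rec)
    table_motif = {f"{fam}:{dist}_disturbance:m{motif}": _score_entry(v)
                   for (fam, dist, motif), v in sorted(by_motif.items())}

    ctype: dict = {}
    for rec in dep:
        kind = "inflow" if rec.motif <= 4 else "outflow"
        one = rec.case_id in ("B1", "B2", "B3", "B4", "B5", "B6", "A1", "A2")
        ctype.setdefault((rec.family, "one" if one else "two", kind), []).append(rec)
    table_ctype = {f"{fam}:{dist}_disturbance:{kind}": _score_entry(v)
                   for (fam, dist, kind), v in sorted(ctype.items())}

    comparison = {}
    comparable = {"basic": ("B2", "B5", "B8", "B11"),
                  "antithetic": ("A1", "A2", "A3", "A4")}
    for fam, fam_cases in comparable.items():
        subset = [r for r in records
                  if r.family == fam and r.case_id in fam_cases
                  and r.category != "always_insufficient"]
        if subset:
            comparison[fam] = _score_entry(subset)

    return {
        "by_case": table_case,
        "by_motif": table_motif,
        "by_controller_type": table_ctype,
        "comparison": comparison,
    }
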