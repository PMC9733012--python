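"""Three-level indicator hierarchy: data model, I/O, validation, revision.

The GOH-IDI framework is a tree of indicators on three levels — first-level
(selective codes, e.g. "Human Health"), second-level (axial codes, e.g.
"Infectious Diseases") and third-level (open codes, e.g. "Tuberculosis").
Each node carries a weight relative to its sibling group, so weights within
any sibling group sum to 1. Parentage is implicit in the dotted code: the
parent of ``"1.2.3"`` is ``"1.2"``.

Serialization is a flat JSON node list (or a CSV mirror) storing weights as
two-decimal percentages, the convention used in published framework tables;
internally weights are fractions in [0, 1].
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, FrameworkValidationError, RevisionError

CATEGORIES = ("structure", "process", "outcome", "none")

#: Default tolerance on sibling-group weight sums (as fractions). Tables
#: printed at two-decimal percent precision accumulate up to ~0.04 pp of
#: truncation per group (e.g. 7 x 14.28 = 99.96), hence 5e-4.
WEIGHT_SUM_TOL = 5e-4


@dataclass
class IndicatorNode:
    """One indicator: dotted code, display name, level, category tag, weight.

    ``weight`` is the node's share within its sibling group, a fraction in
    [0, 1]. ``category`` is an inert structure/process/outcome tag; it plays
    no role in any computation.
    """

    code: str
    name: str
    level: int
    category: str = "none"
    weight: float = 0.0
    extra: dict = field(default_factory=dict)

    @property
    def parent_code(self) -> str | None:
        parts = self.code.split(".")
        return ".".join(parts[:-1]) if len(parts) > 1 else None

    def check(self) -> list[str]:
        problems = []
        if len(self.code.split(".")) != self.level:
            problems.append(f"{self.code}: code depth != level {self.level}")
        if self.level not in (1, 2, 3):
            problems.append(f"{self.code}: level must be 1, 2 or 3")
        if not 0.0 <= self.weight <= 1.0 + 1e-12:
            problems.append(f"{self.code}: weight {self.weight} outside [0, 1]")
        if self.category not in CATEGORIES:
            problems.append(f"{self.code}: unknown category {self.category!r}")
        return problems


@dataclass
class IndicatorFramework:
    """Ordered collection of :class:`IndicatorNode` forming a 3-level tree."""

    nodes: dict[str, IndicatorNode]
    name: str = "indicator framework"
    version: str = "1.0"

    def __post_init__(self):
        codes = list(self.nodes)
        if len(set(codes)) != len(codes):
            raise FrameworkValidationError("duplicate codes in framework")

    # -- structure helpers -------------------------------------------------

    def children(self, code: str | None) -> list[IndicatorNode]:
        if code is None:
            return [n for n in self.nodes.values() if n.level == 1]
        return [n for n in self.nodes.values() if n.parent_code == code]

    def leaves(self) -> list[IndicatorNode]:
        return [n for n in self.nodes.values() if n.level == 3]

    def level_counts(self) -> tuple[int, int, int]:
        counts = [0, 0, 0]
        for n in self.nodes.values():
            counts[n.level - 1] += 1
        return tuple(counts)

    def sibling_groups(self) -> dict[str | None, list[IndicatorNode]]:
        """Map parent code (None for the root group) -> ordered children."""
        groups: dict[str | None, list[IndicatorNode]] = {}
        for n in self.nodes.values():
            groups.setdefault(n.parent_code, []).append(n)
        return groups

    def copy(self) -> "IndicatorFramework":
        return IndicatorFramework(
            nodes={c: replace(n, extra=dict(n.extra)) for c, n in self.nodes.items()},
            name=self.name,
            version=self.version,
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_framework`: counts, sums, verdict."""

    level_counts: tuple[int, int, int]
    group_weight_sums: dict[str, float]  # parent code ("" for root) -> sum
    problems: list[str]

    @property
    def passed(self) -> bool:
        return not self.problems

    def summary(self) -> str:
        counts = "/".join(str(c) for c in self.level_counts)
        verdict = "pass" if self.passed else "FAIL"
        lines = [f"{counts}, {verdict}"]
        lines += [f"  problem: {p}" for p in self.problems]
        return "\n".join(lines)


@dataclass
class RevisionOp:
    """One framework revision: add, delete, merge or rename.

    * ``add``    — insert a leaf; ``code`` and ``name`` required.
    * ``delete`` — remove each target node and its subtree.
    * ``merge``  — replace >= 2 sibling targets with one destination node
      (``code``/``name``) inheriting the union of their children.
    * ``rename`` — change the display name of the single target.
    """

    kind: str
    targets: list[str] = field(default_factory=list)
    code: str | None = None
    name: str | None = None
    category: str = "none"

    def check(self) -> None:
        if self.kind not in ("add", "delete", "merge", "rename"):
            raise RevisionError(f"unknown revision kind {self.kind!r}")
        if self.kind == "add" and not (self.code and self.name):
            raise RevisionError("add requires both code and name")
        if self.kind == "merge" and (len(self.targets) < 2 or not self.code):
            raise RevisionError("merge requires >=2 source codes and a destination")
        if self.kind in ("delete", "rename") and not self.targets:
            raise RevisionError(f"{self.kind} requires at least one target")


# ---------------------------------------------------------------------------
# Loading / writing


def _nodes_from_records(records: Iterable[Mapping]) -> dict[str, IndicatorNode]:
    known = {"code", "name", "level", "category", "weight_percent"}
    nodes: dict[str, IndicatorNode] = {}
    for rec in records:
        try:
            code = str(rec["code"]).strip()
            node = IndicatorNode(
                code=code,
                name=str(rec["name"]).strip(),
                level=int(rec["level"]),
                category=str(rec.get("category") or "none").strip() or "none",
                weight=float(rec["weight_percent"]) / 100.0,
                extra={
                    k: rec[k]
                    for k in rec
                    if k not in known and rec[k] not in (None, "")
                },
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"bad node record {dict(rec)!r}: {exc}") from exc
        if code in nodes:
            raise FormatError(f"duplicate code {code!r} in source")
        nodes[code] = node
    return nodes


def load_framework(source: str | Path) -> IndicatorFramework:
    """Load a framework from a JSON or CSV file (or raw JSON/CSV text).

    JSON schema: ``{"name": ..., "version": ..., "nodes": [{code, name,
    level, category, weight_percent, ...}, ...]}``. The CSV mirror carries
    the columns ``code,name,level,category,weight_percent``. Percentages are
    converted to fractions on load. Raises :class:`FormatError` on parse
    failure and :class:`FrameworkValidationError` when invariants fail.
    """
    path = Path(source) if not str(source).lstrip().startswith(("{", "[")) else None
    if path is not None:
        try:
            text = path.read_text(encoding="utf-8")
        except OSError as exc:
            raise FormatError(f"cannot read {source}: {exc}") from exc
        is_json = path.suffix.lower() == ".json" or text.lstrip().startswith("{")
    else:
        text = str(source)
        is_json = True
    if not text.strip():
        raise FormatError("empty framework source")

    if is_json:
        try:
            doc = json.loads(text)
            records = doc["nodes"]
            meta_name = doc.get("name", "indicator framework")
            meta_version = str(doc.get("version", "1.0"))
        except (json.JSONDecodeError, TypeError, KeyError) as exc:
            raise FormatError(f"invalid framework JSON: {exc}") from exc
    else:
        try:
            reader = csv.DictReader(io.StringIO(text))
            records = list(reader)
        except csv.Error as exc:
            raise FormatError(f"invalid framework CSV: {exc}") from exc
        if not records or "code" not in (reader.fieldnames or []):
            raise FormatError("framework CSV must have a 'code' column header")
        meta_name, meta_version = "indicator framework", "1.0"

    fw = IndicatorFramework(_nodes_from_records(records), meta_name, meta_version)
    report = validate_framework(fw)
    if not report.passed:
        raise FrameworkValidationError(
            "framework fails validation:\n" + "\n".join(report.problems),
            problems=report.problems,
        )
    return fw


def write_framework(fw: IndicatorFramework, path: str | Path) -> Path:
    """Write a framework to JSON or CSV (by extension); round-trips exactly."""
    path = Path(path)
    records = [
        {
            "code": n.code,
            "name": n.name,
            "level": n.level,
            "category": n.category,
            "weight_percent": round(n.weight * 100.0, 10),
            **n.extra,
        }
        for n in fw.nodes.values()
    ]
    if path.suffix.lower() == ".csv":
        fields = ["code", "name", "level", "category", "weight_percent"]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
            writer.writeheader()
            writer.writerows(records)
    else:
        doc = {"name": fw.name, "version": fw.version, "nodes": records}
        path.write_text(json.dumps(doc, indent=1, ensure_ascii=False), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Validation


def validate_framework(
    fw: IndicatorFramework, tol: float = WEIGHT_SUM_TOL
) -> ValidationReport:
    """Check structural invariants; always returns a report, never raises.

    Checks: per-node invariants, unique parentage (every non-level-1 node has
    an existing parent one level up), level-3 nodes are leaves by
    construction, every level-2 node has at least one child, and every
    sibling group's weights sum to 1 within ``tol``.
    """
    problems: list[str] = []
    for node in fw.nodes.values():
        problems += node.check()
        parent = node.parent_code
        if parent is not None and parent not in fw.nodes:
            problems.append(f"{node.code}: parent {parent} missing")

    sums: dict[str, float] = {}
    for parent, members in fw.sibling_groups().items():
        s = sum(n.weight for n in members)
        sums[parent or ""] = s
        if abs(s - 1.0) > tol:
            problems.append(
                f"group under {parent or 'root'}: weights sum to {s:.4f}, not 1"
            )
    for node in fw.nodes.values():
        if node.level == 2 and not fw.children(node.code):
            problems.append(f"{node.code}: second-level node has no children")
    return ValidationReport(fw.level_counts(), sums, problems)


# ---------------------------------------------------------------------------
# Revision


def _renormalize_group(members: Sequence[IndicatorNode]) -> None:
    total = sum(n.weight for n in members)
    if total <= 0:
        for n in members:
            n.weight = 1.0 / len(members)
    else:
        for n in members:
            n.weight /= total


def _renumber(fw: IndicatorFramework) -> IndicatorFramework:
    """Compact sibling codes to 1..k depth-first, preserving order."""
    mapping: dict[str, str] = {}

    def walk(parent_old: str | None, parent_new: str | None):
        for idx, child in enumerate(fw.children(parent_old), start=1):
            new = f"{parent_new}.{idx}" if parent_new else str(idx)
            mapping[child.code] = new
            walk(child.code, new)

    walk(None, None)
    new_nodes = {}
    for code, node in fw.nodes.items():
        new_nodes[mapping[code]] = replace(node, code=mapping[code])
    return IndicatorFramework(new_nodes, fw.name, fw.version)


def apply_revisions(
    fw: IndicatorFramework,
    ops: Sequence[RevisionOp],
    renumber: bool = False,
    renormalize: bool = True,
) -> IndicatorFramework:
    """Apply revision operations in order; returns a new framework.

    ``delete`` removes the node and its whole subtree. ``merge`` keeps the
    sources' children (recoded under the destination, source order
    preserved) and gives the destination the sources' combined weight.
    Sibling groups whose membership changed are renormalized to sum to 1
    (proportional rescaling) unless ``renormalize=False``. With
    ``renumber=True`` sibling codes are compacted to 1..k afterwards.
    """
    out = fw.copy()
    touched: set[str | None] = set()

    for op in ops:
        op.check()
        if op.kind == "add":
            if op.code in out.nodes:
                raise RevisionError(f"add: code {op.code} already exists")
            node = IndicatorNode(
                code=op.code,
                name=op.name,
                level=len(op.code.split(".")),
                category=op.category,
            )
            if node.parent_code is not None and node.parent_code not in out.nodes:
                raise RevisionError(f"add: parent of {op.code} not in framework")
            siblings = out.children(node.parent_code)
            node.weight = 1.0 / (len(siblings) + 1)
            out.nodes[op.code] = node
            touched.add(node.parent_code)
        elif op.kind == "delete":
            for target in op.targets:
                if target not in out.nodes:
                    raise RevisionError(f"delete: unknown code {target}")
                doomed = [
                    c
                    for c in out.nodes
                    if c == target or c.startswith(target + ".")
                ]
                touched.add(out.nodes[target].parent_code)
                for c in doomed:
                    del out.nodes[c]
        elif op.kind == "rename":
            for target in op.targets:
                if target not in out.nodes:
                    raise RevisionError(f"rename: unknown code {target}")
                out.nodes[target].name = op.name or out.nodes[target].name
        elif op.kind == "merge":
            sources = []
            for target in op.targets:
                if target not in out.nodes:
                    raise RevisionError(f"merge: unknown code {target}")
                sources.append(out.nodes[target])
            parents = {s.parent_code for s in sources}
            if len(parents) != 1:
                raise RevisionError("merge: sources must share one parent")
            if op.code in out.nodes and op.code not in op.targets:
                raise RevisionError(f"merge: destination {op.code} already exists")
            dest = IndicatorNode(
                code=op.code,
                name=op.name or sources[0].name,
                level=sources[0].level,
                category=op.category,
                weight=sum(s.weight for s in sources),
            )
            # Union of child subtrees, recoded under the destination in
            # source order; the merged node inherits all surviving leaves.
            moved: list[tuple[str, IndicatorNode]] = []
            counter = 0
            for s in sources:
                for child in out.children(s.code):
                    counter += 1
                    new_code = f"{dest.code}.{counter}"
                    moved.append((child.code, replace(child, code=new_code)))
            rebuilt: dict[str, IndicatorNode] = {}
            inserted = False
            moved_old = {old for old, _ in moved}
            source_codes = {s.code for s in sources}
            for code, node in out.nodes.items():
                if code in source_codes:
                    if not inserted:
                        rebuilt[dest.code] = dest
                        for _, new_node in moved:
                            rebuilt[new_node.code] = new_node
                        inserted = True
                    continue
                if code in moved_old:
                    continue
                rebuilt[code] = node
            out = IndicatorFramework(rebuilt, out.name, out.version)
            touched.add(parents.pop())
            touched.add(dest.code)  # pooled children need renormalizing too

    if renormalize:
        groups = out.sibling_groups()
        for parent in touched:
            if parent in groups:
                _renormalize_group(groups[parent])
    if renumber:
        out = _renumber(out)
    return out


def load_revision_log(source: str | Path) -> list[RevisionOp]:
    """Read a JSON revision log: a list of op objects in application order."""
    text = Path(source).read_text(encoding="utf-8")
    try:
        raw = json.loads(text)
        ops = [
            RevisionOp(
                kind=item["kind"],
                targets=list(item.get("targets", [])),
                code=item.get("code"),
                name=item.get("name"),
                category=item.get("category", "none"),
            )
            for item in raw
        ]
    except (json.JSONDecodeError, TypeError, KeyError) as exc:
        raise FormatError(f"invalid revision log: {exc}") from exc
    for op in ops:
        op.check()
    return ops


# ---------------------------------------------------------------------------
# Equal-weight convention


def equal_weight_allocation(n: int) -> list[float]:
    """Equal weights 1/n for a sibling group of ``n`` indicators.

    The convention used at the first and third levels of the hierarchy:
    every sibling gets the same share. Values are full-precision fractions;
    the last element absorbs float rounding so the sum is exactly 1.
    """
    if not isinstance(n, int) or n < 1:
        raise ValueError(f"group size must be a positive integer, got {n!r}")
    weights = [1.0 / n] * n
    weights[-1] = 1.0 - math.fsum(weights[:-1])
    return weights


def format_percent(fraction: float, decimals: int = 2, truncate: bool = False) -> float:
    """Render a fraction as a percentage at table precision.

    Published framework tables truncate rather than round in places (1/7 is
    printed 14.28); ``truncate=True`` reproduces that style.
    """
    pct = fraction * 100.0
    scale = 10**decimals
    if truncate:
        return math.floor(pct * scale + 1e-9) / scale
    # round half up, the convention of the report tables
    return math.floor(pct * scale + 0.5) / scale


# ---------------------------------------------------------------------------
# Packaged fixtures

_DATA_DIR = Path(__file__).parent / "data"


def packaged_path(name: str) -> Path:
    """Path of a packaged data file (framework fixtures, revision log)."""
    p = _DATA_DIR / name
    if not p.exists():
        raise FileNotFoundError(f"no packaged data file {name!r}")
    return p


def load_final_framework() -> IndicatorFramework:
    """The published final GOH-IDI framework: 3 / 15 / 61 indicators."""
    return load_framework(packaged_path("goh_idi_final.json"))


def load_initial_framework() -> IndicatorFramework:
    """Reconstructed pre-revision framework: 3 / 19 / 79 indicators.

    The open-code placements under the later-deleted axial codes are a
    synthetic reconstruction (the published record lists what was deleted
    but not which group each deleted open code sat in).
    """
    return load_framework(packaged_path("goh_idi_initial.json"))


def load_packaged_revision_log() -> list[RevisionOp]:
    """The documented expert-revision log taking 3/19/79 to 3/15/61."""
    return load_revision_log(packaged_path("revision_log.json"))
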