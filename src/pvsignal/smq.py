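"""Standardized MedDRA Query (SMQ) hierarchy and event membership.

An SMQ groups MedDRA preferred terms (PTs) describing one medical-condition
area; SMQs may nest, and a parent's effective term set is the union of its
own terms and all descendants'. A report is an event for an SMQ when its
reaction set intersects the SMQ's effective terms — at most once per SMQ,
however many reactions match.

Catalog files are YAML, one record per node::

    - name: biliary disorders
      parent: null
      terms: []
    - name: gallstone related disorders
      parent: biliary disorders
      terms:
        - pt: cholelithiasis
          scope: narrow
        - cholecystolithiasis        # bare string -> scope "narrow"

PT matching is exact string equality on case-folded, trimmed text; there is
no fuzzy matching. Because licensed MedDRA SMQ term lists cannot be
redistributed, the bundled catalog carries synthetic term lists on the real
hierarchy topology; users supply real lists in the same format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .reports import AEReport

__all__ = [
    "SmqNode",
    "SmqCatalog",
    "load_catalog",
    "bundled_biliary_catalog",
]

SCOPES = ("narrow", "broad")


@dataclass(frozen=True)
class SmqNode:
    """One SMQ: a name, an optional parent, and scope-tagged preferred terms."""

    name: str
    parent: str | None
    terms: frozenset[tuple[str, str]] = frozenset()  # (pt, scope)

    def own_terms(self, scope: str | None = None) -> frozenset[str]:
        return frozenset(pt for pt, s in self.terms if scope is None or s == scope)


def _norm(text: str) -> str:
    return text.strip().casefold()


class SmqCatalog:
    """A validated tree of SMQ nodes with child-to-parent term rollup."""

    def __init__(self, nodes: Iterable[SmqNode]) -> None:
        self.nodes: dict[str, SmqNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ValueError(f"duplicate SMQ name {node.name!r}")
            self.nodes[node.name] = node
        self.children: dict[str, list[str]] = {name: [] for name in self.nodes}
        roots = []
        for node in self.nodes.values():
            if node.parent is None:
                roots.append(node.name)
            else:
                if node.parent not in self.nodes:
                    raise ValueError(
                        f"SMQ {node.name!r} references unknown parent {node.parent!r}"
                    )
                self.children[node.parent].append(node.name)
        if len(roots) != 1:
            raise ValueError(f"catalog must have exactly one root, found {roots}")
        self.root = roots[0]
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            name = stack.pop()
            if name in seen:
                raise ValueError(f"cycle in SMQ hierarchy at {name!r}")
            seen.add(name)
            stack.extend(self.children[name])
        stray = set(self.nodes) - seen
        if stray:
            # nodes with a parent chain that never reaches the root form a cycle
            raise ValueError(f"cycle or disconnected SMQ nodes: {sorted(stray)}")

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def descendants(self, name: str) -> list[str]:
        if name not in self.nodes:
            raise KeyError(f"unknown SMQ {name!r}")
        out: list[str] = []
        stack = list(self.children[name])
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children[n])
        return out

    def effective_terms(self, name: str, scope: str | None = None) -> frozenset[str]:
        """Union of a node's own terms and all descendants' terms.

        ``scope`` restricts to narrow- or broad-tagged terms; the default
        includes every term.
        """
        if name not in self.nodes:
            raise KeyError(f"unknown SMQ {name!r}")
        terms = set(self.nodes[name].own_terms(scope))
        for child in self.descendants(name):
            terms |= self.nodes[child].own_terms(scope)
        return frozenset(terms)

    def report_matches(
        self, report: AEReport, name: str, scope: str | None = None
    ) -> bool:
        """True iff the report's reactions intersect the SMQ's effective terms."""
        terms = self.effective_terms(name, scope)
        return any(_norm(rx) in terms for rx in report.reactions)

    def count_matching(
        self, reports: Iterable[AEReport], name: str, scope: str | None = None
    ) -> int:
        """Number of reports matching the SMQ; each report counts at most once."""
        terms = self.effective_terms(name, scope)
        return sum(1 for r in reports if any(_norm(rx) in terms for rx in r.reactions))


def _parse_terms(raw: list) -> frozenset[tuple[str, str]]:
    terms = []
    for item in raw or []:
        if isinstance(item, str):
            pt, scope = item, "narrow"
        else:
            pt, scope = item["pt"], item.get("scope", "narrow")
        if scope not in SCOPES:
            raise ValueError(f"unknown term scope {scope!r} for PT {pt!r}")
        terms.append((_norm(pt), scope))
    return frozenset(terms)


def load_catalog(path: str | Path) -> SmqCatalog:
    """Load and validate an SMQ catalog from a YAML file."""
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError("catalog file must contain a list of node records")
    nodes = [
        SmqNode(
            name=rec["name"].strip(),
            parent=(rec.get("parent") or None) and rec["parent"].strip(),
            terms=_parse_terms(rec.get("terms")),
        )
        for rec in raw
    ]
    return SmqCatalog(nodes)


def bundled_biliary_catalog() -> SmqCatalog:
    """The bundled biliary-disorders catalog (synthetic term lists).

    Topology: one root, "biliary disorders", with nine sub-SMQs covering
    malignant and benign biliary tumours, investigations/signs/symptoms,
    tract, congenital, gallbladder, gallstone and infectious disorders.
    The PT lists are synthetic stand-ins for the licensed MedDRA lists.
    """
    ref = resources.files("pvsignal.data") / "smq_biliary_synthetic.yaml"
    with resources.as_file(ref) as path:
        return load_catalog(path)
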