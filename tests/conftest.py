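"""Shared fixtures: tiny hand-built ontologies, random DAGs with a
brute-force closure oracle, and a default synthetic bundle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gofuse.ontology import parse_obo
from gofuse.simulate import FixtureConfig, generate

NS = {"MF": "molecular_function", "BP": "biological_process",
      "CC": "cellular_component"}


def make_obo(terms: dict[str, tuple[str, list[str]]], obsolete: list[str] = (),
             alt_ids: dict[str, str] | None = None) -> str:
    """Build OBO text from {term: (aspect, [parent terms])}."""
    out = ["format-version: 1.2", "ontology: go", ""]
    rev_alt: dict[str, list[str]] = {}
    for alt, primary in (alt_ids or {}).items():
        rev_alt.setdefault(primary, []).append(alt)
    for t, (aspect, parents) in terms.items():
        out += [f"[Term]", f"id: {t}", f"name: {t}", f"namespace: {NS[aspect]}"]
        for alt in rev_alt.get(t, []):
            out.append(f"alt_id: {alt}")
        for p in parents:
            out.append(f"is_a: {p}")
        out.append("")
    for t in obsolete:
        out += [f"[Term]", f"id: {t}", f"name: {t}",
                f"namespace: {NS['MF']}", "is_obsolete: true", ""]
    return "\n".join(out) + "\n"


def go(i: int) -> str:
    return f"GO:{i:07d}"


def random_dag_obo(rng: np.random.Generator, n_terms: int, aspect: str = "MF"):
    """A random single-aspect DAG plus its edge list for oracle closures."""
    terms = {go(1): (aspect, [])}
    edges = []
    for i in range(2, n_terms + 1):
        n_parents = 1 + int(rng.random() < 0.4)
        parents = rng.choice(i - 1, size=min(n_parents, i - 1), replace=False)
        plist = [go(int(p) + 1) for p in parents]
        terms[go(i)] = (aspect, plist)
        edges += [(go(i), p) for p in plist]
    return make_obo(terms), edges


def closure_oracle(edges: list[tuple[str, str]], term: str) -> set[str]:
    """Exhaustive path-following transitive closure."""
    parents: dict[str, set[str]] = {}
    for c, p in edges:
        parents.setdefault(c, set()).add(p)
    seen: set[str] = set()
    stack = list(parents.get(term, ()))
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        stack.extend(parents.get(t, ()))
    return seen


@pytest.fixture(scope="session")
def chain_onto():
    """root <- mid <- leaf, MF."""
    return parse_obo(make_obo({
        go(1): ("MF", []), go(2): ("MF", [go(1)]), go(3): ("MF", [go(2)]),
    }))


@pytest.fixture(scope="session")
def diamond_onto():
    """Two paths from leaf to root: shared ancestors counted once."""
    return parse_obo(make_obo({
        go(1): ("MF", []), go(2): ("MF", [go(1)]), go(3): ("MF", [go(1)]),
        go(4): ("MF", [go(2), go(3)]),
    }))


@pytest.fixture(scope="session")
def flat_onto():
    """One MF root with 20 leaf children (for integrator tests)."""
    terms = {go(1): ("MF", [])}
    terms.update({go(i): ("MF", [go(1)]) for i in range(2, 22)})
    return parse_obo(make_obo(terms))


@pytest.fixture(scope="session")
def bundle():
    return generate(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    bundle.write(d)
    return d
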