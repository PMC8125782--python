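import datetime as dt

import networkx as nx
import numpy as np
import pytest

from dpnkit import DPN, ModuleSpec, SimConfig, build_dpn, build_incidence, generate_catalog, generate_records
from dpnkit.atc import parse_atc
from dpnkit.ingest import IncidenceMap

INDEX_DATE = dt.date(2019, 6, 30)


def make_dpn(edges, nodes=None, n_patients=100, level=5):
    """Hand-assemble a DPN from (u, v, Cij) triples and optional (node, Pi)."""
    g = nx.Graph()
    pis = dict(nodes or {})
    for u, v, cij in edges:
        g.add_edge(u, v, Cij=cij)
    for v in g.nodes:
        pis.setdefault(v, n_patients)
    for v, pi in pis.items():
        g.add_node(v, Pi=pi)
    return DPN(level=level, n_patients=n_patients, graph=g)


def incidence_from_sets(sets, level=5):
    """IncidenceMap from {patient: iterable of code strings}."""
    return IncidenceMap(
        level=level,
        sets={p: frozenset(parse_atc(c) for c in codes) for p, codes in sets.items()},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """1,000-patient simulated cohort with default study conditions."""
    return generate_records(SimConfig(n_patients=1000, seed=11, catalog_size=300))


@pytest.fixture(scope="session")
def module_catalog():
    """60-code catalog plus three disjoint planted 5-code modules (tail codes)."""
    catalog = generate_catalog(60, seed=5)
    texts = [c.text for c in catalog]
    mods = tuple(
        ModuleSpec(codes=tuple(texts[40 + 5 * m : 45 + 5 * m]), boost=0.9, share=0.2)
        for m in range(3)
    )
    return catalog, mods


def planted_config(seed, catalog, mods, n_patients=800):
    return SimConfig(
        n_patients=n_patients,
        seed=seed,
        catalog_size=len(catalog),
        catalog_seed=5,
        popularity_exponent=1.2,
        modules=mods,
    )


@pytest.fixture(scope="session")
def planted_dpn(module_catalog):
    """Level-5 DPN from a planted-module simulation (known structure)."""
    catalog, mods = module_catalog
    records = generate_records(planted_config(seed=21, catalog=catalog, mods=mods))
    return build_dpn(build_incidence(records, 5)), mods


def rng(seed=0):
    return np.random.default_rng(seed)
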