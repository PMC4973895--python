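"""Shared fixtures: replay fetchers, bundled architectures, offline guard."""

from __future__ import annotations

import socket

import pytest
from hypothesis import settings

import needleplot as nd
from needleplot import fixtures
from needleplot.errors import TransportError

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def no_network(monkeypatch):
    """Fail loudly if anything in the suite tries to open a socket.

    The whole suite must run offline: fetch operations are exercised
    only against recorded/synthetic replay documents.
    """

    def _blocked(*args, **kwargs):
        raise RuntimeError("network access is disabled in the test suite")

    monkeypatch.setattr(socket.socket, "connect", _blocked)
    yield


class ReplayFetch:
    """Fetch contract backed by a {url-substring: body} mapping.

    Counts calls so cache-transparency tests can assert zero refetches;
    unknown URLs raise :class:`TransportError` like a dead network.
    """

    def __init__(self, responses: dict[str, str]):
        self.responses = responses
        self.calls: list[str] = []

    def __call__(self, url: str) -> str:
        self.calls.append(url)
        for key, body in self.responses.items():
            if key in url:
                return body
        raise TransportError(f"no replay document for {url}")


@pytest.fixture
def replay_fetch():
    return ReplayFetch(
        {
            "gene_exact:TP53": fixtures.bundled_document("uniprot_tp53"),
            "gene_exact:NOTAGENE_XYZ": fixtures.bundled_document("uniprot_empty"),
            "P04637": fixtures.bundled_document("tp53"),
            "P02671": fixtures.bundled_document("fga"),
        }
    )


@pytest.fixture
def tp53_arch():
    return nd.load_architecture_json(fixtures.bundled_document("tp53"))


@pytest.fixture
def fga_arch():
    return nd.load_architecture_json(fixtures.bundled_document("fga"))


@pytest.fixture
def fga_variants():
    """The five modifications drawn on the FGA-like fixture; two of them
    (314, 543) sit in disordered / low-complexity stretches."""
    return nd.parse_variants(["G103R", "S314F", "P543L", "R700C", "W741*"])


@pytest.fixture
def config():
    return nd.DrawConfig()


def assert_no_head_overlap(layout: nd.LollipopLayout) -> None:
    """Brute-force circle-intersection oracle over a produced layout."""
    n = len(layout.x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = layout.x[i] - layout.x[j]
            dy = layout.stem_top[i] - layout.stem_top[j]
            min_dist = layout.radius[i] + layout.radius[j]
            assert dx * dx + dy * dy >= min_dist * min_dist - 1e-6, (
                f"heads {i} and {j} intersect"
            )


def assert_tick_completeness(
    architecture, variants, config, tickset: nd.TickSet
) -> None:
    """Exhaustive oracle: every candidate tick either survives or is
    within collision distance of a surviving tick of >= priority."""
    from needleplot import layout_engine as le

    candidates: dict[int, int] = {}
    for v in variants:
        candidates[v.position] = max(candidates.get(v.position, 0), 3)
    for d in architecture.domains:
        for p in (d.start, d.end):
            candidates[p] = max(candidates.get(p, 0), 2)
    for p in (1, architecture.length):
        candidates.setdefault(p, 1)

    def extent(pos):
        center = le.aa_to_px(pos, architecture.length, config)
        half = le.estimate_text_width(str(pos), config.font_size) / 2
        return center - half, center + half

    surviving = {t.position: t.priority for t in tickset.ticks}
    for pos, prio in candidates.items():
        if pos in surviving:
            assert surviving[pos] == prio
            continue
        left, right = extent(pos)
        blockers = [
            s for s, sp in surviving.items()
            if sp >= prio
            and extent(s)[0] < right + config.min_tick_gap
            and extent(s)[1] > left - config.min_tick_gap
        ]
        assert blockers, f"tick {pos} (priority {prio}) culled with no blocking neighbor"

    # and no two surviving labels actually overlap
    positions = sorted(surviving)
    for a, b in zip(positions, positions[1:]):
        assert extent(a)[1] + config.min_tick_gap <= extent(b)[0] + 1e-9, (
            f"surviving tick labels {a} and {b} overlap"
        )
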