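"""Rate-limited, retrying fetch layer with pluggable backends.

Every remote interaction in the pipeline goes through :class:`Fetcher`,
which enforces NCBI-style politeness: at most ``max_per_second`` requests in
any sliding one-second window (3 by default, NCBI's documented limit without
an API key) and exponential-backoff retries for transient failures. Two
backends implement the wire contract: :class:`LiveBackend` talks HTTP to the
real NCBI/EBI services; :class:`FixtureBackend` serves a generated offline
corpus and never opens a socket. All requests are sequential.
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.parse
import urllib.request
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol

from .errors import FetchError, ValidationError

ENDPOINTS = frozenset({
    "geo_search", "geo_miniml", "ae_search", "ae_experiment",
    "ae_protocol", "pubmed_summary",
})

#: GEO esearch (db=gds) encodes series GSEn as UID 200000000 + n.
GEO_SERIES_UID_BASE = 200_000_000


@dataclass(frozen=True)
class FetchRequest:
    """One request: a symbolic endpoint plus an ordered parameter mapping."""

    endpoint: str
    params: tuple[tuple[str, str], ...]

    def __init__(self, endpoint: str, params: dict[str, str] | None = None):
        if endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {endpoint!r}")
        object.__setattr__(self, "endpoint", endpoint)
        object.__setattr__(self, "params", tuple((params or {}).items()))

    def param(self, key: str) -> str | None:
        for k, v in self.params:
            if k == key:
                return v
        return None


class Backend(Protocol):
    def request(self, req: FetchRequest) -> tuple[int, bytes, str]:
        """Return (status, body, media_type). May raise TimeoutError."""
        ...


class RateLimiter:
    """Sliding-window limiter: <= max_per_second issues per 1-second window.

    The clock and sleep functions are injectable so the contract is testable
    with a fake clock; with a deterministic clock the issue times are a pure
    function of the request sequence.
    """

    def __init__(self, max_per_second: int = 3,
                 clock: Callable[[], float] = time.monotonic,
                 sleep: Callable[[float], None] = time.sleep):
        if max_per_second < 1:
            raise ValidationError("max_per_second must be >= 1")
        self.max_per_second = max_per_second
        self._clock = clock
        self._sleep = sleep
        self._issues: deque[float] = deque()

    def acquire(self) -> float:
        """Block until a slot is free; return the issue time."""
        now = self._clock()
        while self._issues and now - self._issues[0] >= 1.0:
            self._issues.popleft()
        if len(self._issues) >= self.max_per_second:
            wait = self._issues[0] + 1.0 - now
            if wait > 0:
                self._sleep(wait)
            now = self._clock()
            while self._issues and now - self._issues[0] >= 1.0:
                self._issues.popleft()
        self._issues.append(now)
        return now


class Fetcher:
    """Rate-limited fetch with retries and an optional per-run memo.

    Transient failures (HTTP 429, 5xx, timeouts) are retried up to
    ``max_retries`` times with exponential backoff (base 0.5 s, doubling);
    other 4xx statuses fail immediately.
    """

    def __init__(self, backend: Backend, limiter: RateLimiter | None = None,
                 max_retries: int = 3, backoff_base: float = 0.5,
                 sleep: Callable[[float], None] = time.sleep,
                 memoize: bool = True):
        self.backend = backend
        self.limiter = limiter or RateLimiter()
        self.max_retries = max_retries
        self.backoff_base = backoff_base
        self._sleep = sleep
        self._memo: dict[FetchRequest, tuple[bytes, str]] | None = {} if memoize else None

    def fetch(self, req: FetchRequest) -> tuple[bytes, str]:
        if self._memo is not None and req in self._memo:
            return self._memo[req]
        attempt = 0
        while True:
            self.limiter.acquire()
            transient, status = False, None
            try:
                status, body, media_type = self.backend.request(req)
            except TimeoutError:
                transient = True
            else:
                if status == 200:
                    if self._memo is not None:
                        self._memo[req] = (body, media_type)
                    return body, media_type
                transient = status == 429 or status >= 500
                if not transient:
                    raise FetchError("non-retryable HTTP status", req.endpoint,
                                     status=status)
            if attempt >= self.max_retries:
                raise FetchError("retries exhausted", req.endpoint,
                                 status=status, transient=True)
            self._sleep(self.backoff_base * (2 ** attempt))
            attempt += 1


_LIVE_URLS = {
    "geo_search": ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi",
                   {"db": "gds", "retmax": "100000"}),
    "geo_miniml": ("https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi",
                   {"targ": "self", "form": "xml", "view": "full"}),
    "ae_search": ("https://www.ebi.ac.uk/arrayexpress/xml/v3/experiments", {}),
    "ae_experiment": ("https://www.ebi.ac.uk/arrayexpress/xml/v3/experiments", {}),
    "ae_protocol": ("https://www.ebi.ac.uk/arrayexpress/xml/v3/protocols", {}),
    "pubmed_summary": ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esummary.fcgi",
                       {"db": "pubmed"}),
}


class LiveBackend:
    """HTTP backend against the public NCBI/EBI endpoints."""

    def __init__(self, timeout: float = 30.0):
        self.timeout = timeout

    def request(self, req: FetchRequest) -> tuple[int, bytes, str]:
        base, fixed = _LIVE_URLS[req.endpoint]
        params = dict(fixed)
        params.update(dict(req.params))
        if req.endpoint in ("ae_experiment", "ae_protocol"):
            ident = params.pop("accession", None) or params.pop("id", "")
            url = f"{base}/{urllib.parse.quote(ident)}"
        else:
            url = base
        if params:
            url += "?" + urllib.parse.urlencode(params)
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                media = resp.headers.get_content_type()
                return resp.status, resp.read(), media
        except urllib.error.HTTPError as exc:
            return exc.code, exc.read() or b"", "text/plain"
        except (urllib.error.URLError, OSError) as exc:  # DNS, conn reset, timeout
            raise TimeoutError(str(exc)) from exc


class FixtureBackend:
    """Serve a generated offline corpus; no socket is ever opened.

    The corpus directory must contain ``index.json`` (the ground-truth
    sidecar) plus the per-record XML documents written by the fixture
    generator. Search endpoints are answered by scanning the sidecar with
    case-insensitive substring matching over title + summary — a documented
    test-world simplification of the remote full-text indexes.
    """

    def __init__(self, fixture_dir: str | Path):
        self.root = Path(fixture_dir)
        index_path = self.root / "index.json"
        if not index_path.is_file():
            raise ValidationError(f"no fixture index at {index_path}")
        self.index = json.loads(index_path.read_text())

    # -- search answering -------------------------------------------------
    @staticmethod
    def _matches(term: str, truth: dict) -> bool:
        hay = (truth["title"] + " " + truth["summary"]).lower()
        return term.lower() in hay

    def _geo_search_xml(self, term: str) -> bytes:
        hits = [acc for acc, t in self.index["geo"].items()
                if self._matches(term, t)]
        ids = "".join(
            f"<Id>{GEO_SERIES_UID_BASE + int(acc[3:])}</Id>" for acc in hits)
        return (f"<eSearchResult><Count>{len(hits)}</Count>"
                f"<IdList>{ids}</IdList></eSearchResult>").encode()

    def _ae_search_xml(self, term: str) -> bytes:
        hits = [acc for acc, t in self.index["ae"].items()
                if self._matches(term, t)]
        body = "".join(f"<experiment><accession>{acc}</accession></experiment>"
                       for acc in hits)
        return (f'<experiments total="{len(hits)}">{body}</experiments>').encode()

    def request(self, req: FetchRequest) -> tuple[int, bytes, str]:
        if req.endpoint == "geo_search":
            return 200, self._geo_search_xml(req.param("term") or ""), "text/xml"
        if req.endpoint == "ae_search":
            return 200, self._ae_search_xml(req.param("keywords") or ""), "text/xml"
        if req.endpoint == "geo_miniml":
            path = self.root / "geo" / f"{req.param('accession')}.xml"
        elif req.endpoint == "ae_experiment":
            path = self.root / "ae" / f"{req.param('accession')}.xml"
        elif req.endpoint == "ae_protocol":
            path = self.root / "ae" / "protocols" / f"{req.param('id')}.xml"
        else:  # pubmed_summary
            ident = req.param("id") or ""
            pmid = self.index.get("doi_to_pmid", {}).get(ident, ident)
            path = self.root / "pubmed" / f"{pmid}.xml"
        if not path.is_file():
            return 404, b"", "text/plain"
        return 200, path.read_bytes(), "text/xml"


def open_fetcher(offline_dir: str | Path | None = None,
                 max_per_second: int | None = None,
                 max_retries: int = 3) -> Fetcher:
    """Build a fetcher over the fixture corpus (offline) or the live services.

    The politeness delay exists to protect the remote services, so the
    default rate is 3/s live but effectively unlimited against a local
    fixture directory; pass ``max_per_second`` to override either.
    """
    backend: Backend
    if offline_dir is not None:
        backend = FixtureBackend(offline_dir)
        limit = max_per_second if max_per_second is not None else 1_000_000
    else:
        backend = LiveBackend()
        limit = max_per_second if max_per_second is not None else 3
    return Fetcher(backend, RateLimiter(limit), max_retries=max_retries)
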