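"""Shared fixtures: tiny terminologies and a mock paged FHIR server."""

from __future__ import annotations

import io
import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import parse_qs, urlparse

import pytest

from rddq.terminology import AlphaDialect, parse_alpha_id_se

# Terminology under the default 7-field dialect. Q87.5 carries two fully
# annotated terms (Grant / Lowry-Wood), F84.2 two Rett-syndrome terms,
# G71.2 one annotated term, E84.0 has a term lacking an Orphacode.
DEFAULT_DIALECT_LINES = """\
1|I128560|Q87.5|||2097|Grant syndrome
1|I128737|Q87.5|||1824|Lowry-Wood syndrome
1|I200001|F84.2|||778|Rett syndrome
1|I200002|F84.2|||3095|Atypical Rett syndrome
1|I200003|G71.2|||53698|Congenital myopathy
1|I200004|E84.0|||586|Cystic fibrosis pulmonary
1|I200005|E84.0||||Cystic fibrosis unspecified term
0|I200006|E84.0|||12345|Retired cystic fibrosis term
"""


@pytest.fixture()
def small_terminology():
    return parse_alpha_id_se(io.StringIO(DEFAULT_DIALECT_LINES))


#: 6-field layout used by some terminology exports (no additional-code field)
SIX_FIELD_DIALECT = AlphaDialect(valid=0, alpha_id=1, icd_primary=2, icd_star=3,
                                 orphacode=4, label=5)


class _FhirHandler(BaseHTTPRequestHandler):
    server_version = "MockFHIR/1"

    def log_message(self, *args):  # keep test output clean
        pass

    def do_GET(self):
        parsed = urlparse(self.path)
        rtype = parsed.path.strip("/").split("/")[-1]
        params = parse_qs(parsed.query)
        count = int(params.get("_count", ["100"])[0])
        offset = int(params.get("_getpagesoffset", ["0"])[0])
        fail_map = self.server.fail_once  # type: ignore[attr-defined]
        key = (rtype, offset)
        if fail_map.get(key, 0) > 0:
            fail_map[key] -= 1
            self.send_response(500)
            self.end_headers()
            self.wfile.write(b"transient failure")
            return
        resources = self.server.resources.get(rtype, [])  # type: ignore[attr-defined]
        page = resources[offset:offset + count]
        bundle = {
            "resourceType": "Bundle",
            "type": "searchset",
            "total": len(resources),
            "entry": [{"resource": r} for r in page],
        }
        body = json.dumps(bundle).encode()
        self.send_response(200)
        self.send_header("Content-Type", "application/fhir+json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)


class MockFhirServer:
    """Paged FHIR search endpoint backed by in-memory resource lists."""

    def __init__(self, resources: dict[str, list[dict]], fail_once: dict | None = None):
        self._httpd = ThreadingHTTPServer(("127.0.0.1", 0), _FhirHandler)
        self._httpd.resources = resources  # type: ignore[attr-defined]
        self._httpd.fail_once = dict(fail_once or {})  # type: ignore[attr-defined]
        self._thread = threading.Thread(target=self._httpd.serve_forever, daemon=True)
        self._thread.start()

    @property
    def url(self) -> str:
        host, port = self._httpd.server_address
        return f"http://{host}:{port}"

    def close(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()


@pytest.fixture()
def mock_fhir_server():
    servers = []

    def factory(resources, fail_once=None):
        server = MockFhirServer(resources, fail_once)
        servers.append(server)
        return server

    yield factory
    for server in servers:
        server.close()
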