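"""Stdlib WSGI facade over the CDS manager.

Routes:

- ``GET  /cds-services``        CDS Hooks 1.0 discovery
- ``POST /cds-services/{id}``   service invocation, returns ``{"cards": [...]}``
- ``GET  /health``              health status
- ``POST /event``               event ingestion
- ``GET  /stats``               per-service usage counters

The application is a plain WSGI callable, servable with
``wsgiref.simple_server`` and testable entirely in-process.
"""

from __future__ import annotations

import json

from ..errors import AdapterError, NotFoundError, ParseError
from .service import CDSManager


def make_wsgi_app(manager: CDSManager):
    def app(environ, start_response):
        method = environ.get("REQUEST_METHOD", "GET")
        path = environ.get("PATH_INFO", "/")
        try:
            status, body = _route(manager, method, path, _read_body(environ))
        except NotFoundError as exc:
            status, body = "404 Not Found", {"error": str(exc)}
        except (ParseError, AdapterError, ValueError) as exc:
            status, body = "400 Bad Request", {"error": str(exc)}
        except Exception as exc:  # engine failure: logged by the manager
            status, body = "500 Internal Server Error", {"error": str(exc)}
        payload = json.dumps(body).encode("utf-8")
        start_response(
            status,
            [
                ("Content-Type", "application/json; charset=utf-8"),
                ("Content-Length", str(len(payload))),
            ],
        )
        return [payload]

    return app


def _read_body(environ) -> dict | None:
    try:
        length = int(environ.get("CONTENT_LENGTH") or 0)
    except ValueError:
        length = 0
    if length <= 0:
        return None
    raw = environ["wsgi.input"].read(length)
    try:
        return json.loads(raw.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ParseError(f"malformed JSON request body: {exc}") from exc


def _route(manager: CDSManager, method: str, path: str, body):
    if method == "GET" and path == "/cds-services":
        return "200 OK", manager.discovery()
    if method == "POST" and path.startswith("/cds-services/"):
        service_id = path[len("/cds-services/"):]
        if not service_id:
            raise NotFoundError("missing service id")
        if body is None:
            raise ParseError("invocation requires a JSON request body")
        cards = manager.proxy_call(service_id, body)
        return "200 OK", {"cards": [c.to_dict() for c in cards]}
    if method == "GET" and path == "/health":
        return "200 OK", manager.health_check().to_dict()
    if method == "POST" and path == "/event":
        manager.post_event(body or {})
        return "200 OK", {"accepted": True}
    if method == "GET" and path == "/stats":
        return "200 OK", manager.stats()
    raise NotFoundError(f"no route for {method} {path}")
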