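import datetime as dt
import io
import json

import pytest

from fhircds.facts import Fact, Quantity
from fhircds.fixtures import demo_respiratory_model, demo_rule_kb
from fhircds.terminology import LOINC, CodedConcept

T0 = dt.datetime(2024, 3, 1, 12, 0, tzinfo=dt.timezone.utc)


def make_fact(code, value, unit="", subject="p1", minutes=0, system=LOINC, status=None):
    """Terse fact constructor for tests."""
    from fhircds.facts import FactStatus

    if isinstance(value, (int, float)) and not isinstance(value, bool):
        value = Quantity(float(value), unit)
    return Fact(
        subject_id=subject,
        concept=CodedConcept(system, code),
        value=value,
        effective_time=T0 + dt.timedelta(minutes=minutes),
        status=status or FactStatus.FINAL,
    )


@pytest.fixture(scope="session")
def demo_kb():
    return demo_rule_kb()


@pytest.fixture(scope="session")
def respiratory_model():
    return demo_respiratory_model()


def call_wsgi(app, method, path, body=None):
    """Invoke a WSGI app in-process; returns (status code, decoded JSON)."""
    captured = {}
    environ = {"REQUEST_METHOD": method, "PATH_INFO": path}
    if body is not None:
        raw = json.dumps(body).encode("utf-8")
        environ["CONTENT_LENGTH"] = str(len(raw))
        environ["wsgi.input"] = io.BytesIO(raw)

    def start_response(status, headers):
        captured["status"] = int(status.split()[0])

    payload = b"".join(app(environ, start_response))
    return captured["status"], json.loads(payload)
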