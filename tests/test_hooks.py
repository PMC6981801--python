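"""CDS Hooks 1.0 conformance, card mapping, proxy statistics, health, WSGI."""

import pytest

from conftest import call_wsgi
from fhircds.errors import ModelNotAcceptedError, NotFoundError
from fhircds.fixtures import demo_respiratory_model
from fhircds.hooks import (
    CDSManager,
    CDSServiceDescriptor,
    artifact_to_card,
    make_wsgi_app,
)
from fhircds.hooks.model import CheckStatus, Indicator
from fhircds.hooks.service import truncate_summary
from fhircds.kb import BAYES_MODEL, RULE_KB, KnowledgeStore
from fhircds.bayes.model import ModelValidation, ValidationStatus
from fhircds.rules.model import Artifact, ArtifactType
from fhircds.terminology import LOINC, SNOMED_CT


def observation(code, value, unit, system=LOINC):
    return {
        "resourceType": "Observation",
        "status": "final",
        "code": {"coding": [{"system": system, "code": code}]},
        "subject": {"reference": "Patient/p1"},
        "valueQuantity": {"value": value, "unit": unit},
        "effectiveDateTime": "2024-02-01T09:00:00+00:00",
    }


def bundle(*resources):
    entries = [{"resource": {"resourceType": "Patient", "id": "p1"}}]
    entries += [{"resource": r} for r in resources]
    return {"resourceType": "Bundle", "type": "collection", "entry": entries}


def cds_request(prefetch_bundle=None, patient_id="p1"):
    body = {
        "hook": "patient-view",
        "hookInstance": "instance-1",
        "context": {"patientId": patient_id},
    }
    if prefetch_bundle is not None:
        body["prefetch"] = {"patientData": prefetch_bundle}
    return body


DIABETES_BUNDLE = bundle(
    observation("2345-7", 7.4, "mmol/L"),
    observation("39156-5", 32.0, "kg/m2"),
)

CHILL_CONDITION = {
    "resourceType": "Condition",
    "code": {"coding": [{"system": SNOMED_CT, "code": "43724002"}]},
    "subject": {"reference": "Patient/p1"},
}


@pytest.fixture()
def manager(demo_kb, respiratory_model):
    store = KnowledgeStore()
    store.put_entity(RULE_KB, demo_kb)
    store.put_entity(BAYES_MODEL, respiratory_model)
    mgr = CDSManager(store)
    mgr.register_service(
        CDSServiceDescriptor(
            service_id="demo-rules",
            hook="patient-view",
            title="Lab interpretation rules",
            description="Production-rule interpretation of recent labs",
            engine_kind=RULE_KB,
            engine_id=demo_kb.id,
            prefetch=(("patientData", "Observation?patient={{context.patientId}}"),),
        )
    )
    mgr.register_service(
        CDSServiceDescriptor(
            service_id="respiratory-bayes",
            hook="patient-view",
            title="Respiratory differential",
            description="Bayesian respiratory differential diagnosis",
            engine_kind=BAYES_MODEL,
            engine_id="demo-respiratory",
        )
    )
    return mgr


class TestTruncation:
    def test_short_text_unchanged(self):
        assert truncate_summary("short") == "short"

    def test_long_text_cut_at_word_boundary_with_ellipsis(self):
        text = "word " * 60
        out = truncate_summary(text)
        assert len(out) <= 140
        assert out.endswith("…")
        assert not out[:-1].endswith(" wor")  # no mid-word cut
        assert out[:-1] in text

    def test_exactly_limit_is_untouched(self):
        text = "x" * 140
        assert truncate_summary(text) == text


class TestArtifactToCard:
    @pytest.mark.parametrize(
        "artifact_type, indicator",
        [
            (ArtifactType.RISK, Indicator.WARNING),
            (ArtifactType.DIAGNOSIS, Indicator.INFO),
            (ArtifactType.SCALE, Indicator.INFO),
            (ArtifactType.RECOMMENDATION, Indicator.INFO),
            (ArtifactType.DESCRIPTION, Indicator.INFO),
            (ArtifactType.BEHAVIOR_RECOMMENDATION, Indicator.INFO),
        ],
    )
    def test_indicator_mapping(self, artifact_type, indicator):
        card = artifact_to_card(Artifact("a", artifact_type, "some text"))
        assert card.indicator is indicator

    def test_urgent_diagnosis_is_critical(self):
        art = Artifact("a", ArtifactType.DIAGNOSIS, "sepsis pattern",
                       payload=("urgent",))
        assert artifact_to_card(art).indicator is Indicator.CRITICAL

    @pytest.mark.parametrize(
        "artifact_type",
        [ArtifactType.REFERRAL_REQUEST, ArtifactType.PROCEDURE_REQUEST,
         ArtifactType.DIAGNOSTIC_REQUEST],
    )
    def test_request_types_carry_a_suggestion(self, artifact_type):
        card = artifact_to_card(Artifact("a", artifact_type, "refer to cardiology"))
        assert len(card.suggestions) == 1
        assert card.suggestions[0].label == "refer to cardiology"

    def test_long_text_truncated_with_full_detail(self):
        text = "elevated risk " * 30
        card = artifact_to_card(Artifact("a", ArtifactType.RISK, text))
        assert len(card.summary) <= 140
        assert card.summary.endswith("…")
        assert card.detail == text

    def test_card_dict_shape(self):
        card = artifact_to_card(Artifact("a", ArtifactType.RISK, "risk"), "src")
        doc = card.to_dict()
        assert doc == {"summary": "risk", "indicator": "warning",
                       "source": {"label": "src"}}


class TestRegistry:
    def test_discovery_lists_services_sorted(self, manager):
        doc = manager.discovery()
        ids = [s["id"] for s in doc["services"]]
        assert ids == sorted(ids) == ["demo-rules", "respiratory-bayes"]
        for svc in doc["services"]:
            assert set(svc) >= {"id", "hook", "title", "description"}

    def test_register_replaces_same_id(self, manager, demo_kb):
        manager.register_service(
            CDSServiceDescriptor(
                service_id="demo-rules", hook="order-sign", title="v2",
                description="", engine_kind=RULE_KB, engine_id=demo_kb.id,
            )
        )
        (svc,) = [s for s in manager.discovery()["services"] if s["id"] == "demo-rules"]
        assert svc["hook"] == "order-sign"

    def test_prototype_model_refused_at_registration(self, manager):
        draft = demo_respiratory_model()
        draft.id = "draft-model"
        draft.validation = ModelValidation(ValidationStatus.PROTOTYPE, [])
        manager.store.put_entity(BAYES_MODEL, draft)
        with pytest.raises(ModelNotAcceptedError, match="draft-model"):
            manager.register_service(
                CDSServiceDescriptor(
                    service_id="draft-svc", hook="patient-view", title="",
                    description="", engine_kind=BAYES_MODEL, engine_id="draft-model",
                )
            )

    def test_binding_to_missing_entity_refused(self, manager):
        with pytest.raises(NotFoundError):
            manager.register_service(
                CDSServiceDescriptor(
                    service_id="bad", hook="patient-view", title="",
                    description="", engine_kind=RULE_KB, engine_id="ghost",
                )
            )


class TestInvocation:
    def test_rule_service_fires_diabetes_risk_card(self, manager):
        cards = manager.invoke_service("demo-rules", cds_request(DIABETES_BUNDLE))
        assert any(c.indicator is Indicator.WARNING for c in cards)
        assert any("diabetes" in c.summary.lower() for c in cards)

    def test_normal_labs_yield_empty_card_list(self, manager):
        normal = bundle(observation("2345-7", 5.0, "mmol/L"))
        assert manager.invoke_service("demo-rules", cds_request(normal)) == []

    def test_bayes_service_returns_ranked_diagnosis_card(self, manager):
        cards = manager.invoke_service(
            "respiratory-bayes", cds_request(bundle(CHILL_CONDITION))
        )
        (card,) = cards
        assert card.indicator is Indicator.INFO
        assert card.summary.startswith("Most likely:")
        assert card.detail.count("P(") == 2  # both diagnosis nodes listed

    def test_no_prefetch_falls_back_to_context_patient(self, manager):
        cards = manager.invoke_service("respiratory-bayes", cds_request())
        (card,) = cards  # priors only
        assert "Most likely:" in card.summary

    def test_unknown_service_raises_not_found(self, manager):
        with pytest.raises(NotFoundError):
            manager.invoke_service("ghost-service", cds_request())

    def test_invocation_is_stateless(self, manager):
        first = manager.invoke_service("demo-rules", cds_request(DIABETES_BUNDLE))
        for _ in range(3):
            manager.invoke_service("demo-rules", cds_request(bundle()))
        again = manager.invoke_service("demo-rules", cds_request(DIABETES_BUNDLE))
        assert [c.to_dict() for c in again] == [c.to_dict() for c in first]

    def test_transaction_ids_unique_per_invocation(self, manager):
        for _ in range(5):
            manager.invoke_service("demo-rules", cds_request(DIABETES_BUNDLE))
        ids = [e.transaction_id for e in manager.transaction_log]
        assert len(set(ids)) == len(ids) == 5


class TestProxyStats:
    def test_counters_track_calls_and_cards(self, manager):
        manager.proxy_call("demo-rules", cds_request(DIABETES_BUNDLE))
        manager.proxy_call("demo-rules", cds_request(bundle()))
        stats = manager.stats()["demo-rules"]
        assert stats["calls"] == 2
        assert stats["errors"] == 0
        assert stats["cards"] >= 1

    def test_engine_failure_counts_as_error_and_reraises(self, manager):
        bad = cds_request({"resourceType": "Bundle", "type": "collection",
                           "entry": []}, patient_id=None)
        bad["context"] = {}
        with pytest.raises(Exception):
            manager.proxy_call("demo-rules", bad)
        stats = manager.stats()["demo-rules"]
        assert stats == {"calls": 1, "errors": 1, "cards": 0}
        (entry,) = manager.transaction_log
        assert entry.outcome == "error" and entry.error


class TestHealth:
    def test_all_builtin_checks_pass(self, manager):
        health = manager.health_check()
        assert health.status is CheckStatus.PASS
        assert {c.name for c in health.checks} >= {"store", "disk-space", "catalog"}

    def test_custom_failing_check_degrades_overall_status(self, manager):
        manager.add_health_check("upstream", lambda: (CheckStatus.FAIL, "down"))
        assert manager.health_check().status is CheckStatus.FAIL

    def test_custom_warn_check_yields_warn(self, manager):
        manager.add_health_check("queue", lambda: (CheckStatus.WARN, "backlog"))
        assert manager.health_check().status is CheckStatus.WARN

    def test_raising_check_is_reported_as_fail(self, manager):
        def boom():
            raise RuntimeError("probe exploded")

        manager.add_health_check("probe", boom)
        health = manager.health_check()
        (probe,) = [c for c in health.checks if c.name == "probe"]
        assert probe.status is CheckStatus.FAIL
        assert "probe exploded" in probe.detail

    def test_missing_store_root_fails_store_check(self, demo_kb, tmp_path):
        root = tmp_path / "store"
        store = KnowledgeStore(root)
        store.put_entity(RULE_KB, demo_kb)
        mgr = CDSManager(store)
        import shutil

        shutil.rmtree(root)
        health = mgr.health_check()
        (check,) = [c for c in health.checks if c.name == "store"]
        assert check.status is CheckStatus.FAIL


class TestWsgi:
    @pytest.fixture()
    def app(self, manager):
        return make_wsgi_app(manager)

    def test_discovery_route(self, app):
        status, body = call_wsgi(app, "GET", "/cds-services")
        assert status == 200
        assert [s["id"] for s in body["services"]] == ["demo-rules", "respiratory-bayes"]

    def test_invocation_route_returns_cards(self, app):
        status, body = call_wsgi(
            app, "POST", "/cds-services/demo-rules", cds_request(DIABETES_BUNDLE)
        )
        assert status == 200
        assert body["cards"]
        for card in body["cards"]:
            assert set(card) >= {"summary", "indicator", "source"}
            assert len(card["summary"]) <= 140

    def test_unknown_service_is_404(self, app):
        status, body = call_wsgi(app, "POST", "/cds-services/nope", cds_request())
        assert status == 404

    def test_malformed_request_is_400(self, app):
        status, _ = call_wsgi(app, "POST", "/cds-services/demo-rules",
                              {"context": {}})  # no hook/hookInstance
        assert status == 400

    def test_health_and_stats_routes(self, app, manager):
        manager.proxy_call("demo-rules", cds_request(bundle()))
        status, health = call_wsgi(app, "GET", "/health")
        assert status == 200 and health["status"] == "pass"
        status, stats = call_wsgi(app, "GET", "/stats")
        assert status == 200 and stats["demo-rules"]["calls"] == 1

    def test_event_route_appends_to_log(self, app, manager):
        status, body = call_wsgi(app, "POST", "/event", {"kind": "audit", "n": 1})
        assert status == 200 and body == {"accepted": True}
        assert manager.event_log[-1]["kind"] == "audit"

    def test_unknown_route_is_404(self, app):
        status, _ = call_wsgi(app, "GET", "/nope")
        assert status == 404
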