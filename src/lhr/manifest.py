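"""Source manifest: declarative description of an integration run.

A manifest (YAML or JSON) names the person, each source document with its
kind and service root, and the output file:

.. code-block:: yaml

    person:
      uri: https://example.org/lhr/person/alice
      name: Alice
    sources:
      - path: glucose.ttl
        kind: fhir-rdf          # fhir-rdf | sosa-rdf | semrest-json | linked-data
        format: turtle
        service_root: https://healthcare.example.org/fhir
      - path: steps.json
        kind: semrest-json
        context: steps.context.jsonld   # required for semrest-json
        service_root: https://fitbit.example.org
        mapping: semrest.ttl            # optional extra mapping extension
      - path: climate.ttl
        kind: sosa-rdf
        polarity: env
        service_root: https://home.example.org/wot
    output:
      path: alice.ttl
      format: turtle
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from rdflib import URIRef

from .adapters import SOURCE_KINDS
from .errors import ManifestError


@dataclass
class SourceEntry:
    path: str
    kind: str
    service_root: str
    format: str = "turtle"
    polarity: str | None = None
    context: str | None = None
    mapping: str | None = None


@dataclass
class SourceManifest:
    person_uri: str
    person_name: str | None
    sources: list[SourceEntry]
    output_path: str = "integrated.ttl"
    output_format: str = "turtle"
    base_dir: Path = field(default_factory=Path)

    def resolve(self, p: str) -> Path:
        return self.base_dir / p


def _require(mapping: dict, key: str, path: str) -> object:
    if not isinstance(mapping, dict) or key not in mapping:
        raise ManifestError("required field missing", field=f"{path}.{key}" if path else key)
    return mapping[key]


def parse_manifest(data: dict, base_dir: Path | str = ".") -> SourceManifest:
    """Validate a manifest mapping; raises :class:`ManifestError` naming the
    offending field path."""
    if not isinstance(data, dict):
        raise ManifestError("manifest must be a mapping", field="$")
    person = _require(data, "person", "")
    uri = str(_require(person, "uri", "person"))
    if "://" not in uri:
        raise ManifestError("person.uri must be an absolute URI", field="person.uri")
    name = person.get("name")

    raw_sources = data.get("sources", [])
    if not isinstance(raw_sources, list):
        raise ManifestError("must be a list", field="sources")
    sources: list[SourceEntry] = []
    for i, entry in enumerate(raw_sources):
        where = f"sources[{i}]"
        kind = str(_require(entry, "kind", where))
        if kind not in SOURCE_KINDS:
            raise ManifestError(f"unknown kind {kind!r}", field=f"{where}.kind")
        path = str(_require(entry, "path", where))
        root = str(_require(entry, "service_root", where))
        polarity = entry.get("polarity")
        if polarity is not None and polarity not in ("env", "health"):
            raise ManifestError("must be 'env' or 'health'", field=f"{where}.polarity")
        context = entry.get("context")
        if kind == "semrest-json" and context is None:
            raise ManifestError(
                "semrest-json sources require a JSON-LD context", field=f"{where}.context"
            )
        sources.append(
            SourceEntry(
                path=path,
                kind=kind,
                service_root=root,
                format=str(entry.get("format", "json" if kind == "semrest-json" else "turtle")),
                polarity=polarity,
                context=context,
                mapping=entry.get("mapping"),
            )
        )

    output = data.get("output", {}) or {}
    manifest = SourceManifest(
        person_uri=uri,
        person_name=name,
        sources=sources,
        output_path=str(output.get("path", "integrated.ttl")),
        output_format=str(output.get("format", "turtle")),
        base_dir=Path(base_dir),
    )
    for i, src in enumerate(manifest.sources):
        for attr in ("path", "context", "mapping"):
            rel = getattr(src, attr)
            if rel is not None and not manifest.resolve(rel).exists():
                raise ManifestError(
                    f"file not found: {manifest.resolve(rel)}", field=f"sources[{i}].{attr}"
                )
    return manifest


def load_manifest(path: str | Path) -> SourceManifest:
    """Read and validate a YAML/JSON manifest file."""
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"file not found: {path}", field="manifest")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ManifestError(f"not valid YAML/JSON: {exc}", field="manifest") from exc
    return parse_manifest(data, base_dir=path.parent)


def person_ref(manifest: SourceManifest):
    from .integrator import PersonRef

    return PersonRef(uri=URIRef(manifest.person_uri), name=manifest.person_name)
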