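"""Plugin registry: namespaced pure functions callable from assertions.

A plugin publishes a manifest (unique namespace, mapping of function
names to callables, version).  Registered functions become reachable in
the assertion mini-language as ``<namespace>.<fn>(...)``.  Functions must
be pure — value in, value out, no side effects; violating that is a
contract breach on the plugin author's side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable


class PluginError(RuntimeError):
    pass


@dataclass(frozen=True)
class PluginManifest:
    namespace: str
    functions: dict[str, Callable]
    version: str = "0"


@dataclass
class PluginRegistry:
    manifests: dict[str, PluginManifest] = field(default_factory=dict)

    def register(self, manifest: PluginManifest) -> "PluginRegistry":
        if manifest.namespace in self.manifests:
            raise PluginError(
                f"plugin namespace {manifest.namespace!r} already registered")
        self.manifests[manifest.namespace] = manifest
        return self

    def namespaces(self) -> dict[str, dict[str, Callable]]:
        return {ns: dict(m.functions) for ns, m in self.manifests.items()}


def register_plugin(registry: PluginRegistry,
                    manifest: PluginManifest) -> PluginRegistry:
    return registry.register(manifest)


def default_registry() -> PluginRegistry:
    """Registry preloaded with the bioinformatics format plugins
    (vcf, fasta, fastq, sam, csv namespaces)."""
    from pipetest import bio

    registry = PluginRegistry()
    for fmt in ("vcf", "fasta", "fastq", "sam"):
        registry.register(PluginManifest(
            namespace=fmt,
            functions={
                "summary": _summary_fn(fmt),
                "digest": _digest_fn(fmt),
            },
            version="0.1.0",
        ))
    registry.manifests["vcf"].functions["variant"] = bio.vcf_variant
    registry.register(PluginManifest(
        namespace="csv",
        functions={
            "summary": _summary_fn("table"),
            "digest": _digest_fn("table"),
        },
        version="0.1.0",
    ))
    return registry


def _summary_fn(fmt: str):
    from pipetest import bio

    def summary(path):
        return bio.summarize(_as_path(path), fmt)
    return summary


def _digest_fn(fmt: str):
    from pipetest import bio

    def digest(path):
        return bio.content_digest(_as_path(path), fmt)
    return digest


def _as_path(value):
    from pipetest.channels import FileRef
    if isinstance(value, FileRef):
        return value.path
    return value
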