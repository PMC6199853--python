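"""File-based model/plate registry.

A registry is a directory holding copies of artefact files plus one JSON
manifest per entry, keyed by the file's SHA-256.  Content-addressing makes
re-adding the same file a no-op, and the registry survives process
restarts by construction.  A relational backend would slot in behind the
same two operations.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

__all__ = ["Registry", "RegistryEntry"]


@dataclass
class RegistryEntry:
    sha256: str
    filename: str
    kind: str
    added: str

    def to_json(self) -> dict:
        return {"sha256": self.sha256, "filename": self.filename,
                "kind": self.kind, "added": self.added}


class Registry:
    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _manifest_path(self, sha: str) -> Path:
        return self.root / f"{sha}.entry.json"

    def add(self, path: str | Path, kind: str = "model") -> RegistryEntry:
        """Add a file; identical content is deduplicated by hash."""
        path = Path(path)
        data = path.read_bytes()
        sha = hashlib.sha256(data).hexdigest()
        manifest = self._manifest_path(sha)
        if manifest.exists():
            return RegistryEntry(**json.loads(manifest.read_text()))
        stored = self.root / f"{sha}_{path.name}"
        shutil.copyfile(path, stored)
        entry = RegistryEntry(
            sha256=sha, filename=stored.name, kind=kind,
            added=datetime.now(timezone.utc).isoformat(timespec="seconds"))
        manifest.write_text(json.dumps(entry.to_json(), indent=1) + "\n")
        return entry

    def list(self) -> list[RegistryEntry]:
        entries = []
        for p in sorted(self.root.glob("*.entry.json")):
            entries.append(RegistryEntry(**json.loads(p.read_text())))
        return entries
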