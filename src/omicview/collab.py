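"""Project / user / annotation management on an embedded relational store.

SQLite backs projects, datasets, users, per-project roles, versioned
annotations (cell-type labels, feature renames, comments), shareable
session tokens, and bearer auth tokens.  Annotation "synchronization" is
versioned last-writer-wins: every write appends a new revision, reads
return the latest, and the full history stays queryable.

Roles: ``admin`` (membership + everything), ``editor`` (data + annotation
writes), ``viewer`` (read only).  Every project keeps at least one admin.
"""

from __future__ import annotations

import hashlib
import hmac
import os
import secrets
import sqlite3
import time
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

ROLES = ("admin", "editor", "viewer")

_SCHEMA = """
CREATE TABLE IF NOT EXISTS projects (
    project_id TEXT PRIMARY KEY,
    name TEXT NOT NULL,
    species TEXT,
    assembly TEXT
);
CREATE TABLE IF NOT EXISTS datasets (
    dataset_id TEXT PRIMARY KEY,
    project_id TEXT NOT NULL REFERENCES projects(project_id) ON DELETE CASCADE,
    kind TEXT NOT NULL,           -- track | sc
    format TEXT,
    path TEXT,
    grp TEXT
);
CREATE TABLE IF NOT EXISTS users (
    user_id TEXT PRIMARY KEY,
    name TEXT NOT NULL,
    salt BLOB NOT NULL,
    credential_hash BLOB NOT NULL
);
CREATE TABLE IF NOT EXISTS roles (
    project_id TEXT NOT NULL REFERENCES projects(project_id) ON DELETE CASCADE,
    user_id TEXT NOT NULL REFERENCES users(user_id) ON DELETE CASCADE,
    role TEXT NOT NULL CHECK (role IN ('admin','editor','viewer')),
    PRIMARY KEY (project_id, user_id)
);
CREATE TABLE IF NOT EXISTS annotations (
    project_id TEXT NOT NULL,
    target TEXT NOT NULL,
    kind TEXT NOT NULL CHECK (kind IN ('cell_type_label','feature_rename','comment')),
    revision INTEGER NOT NULL,
    value TEXT NOT NULL,
    author TEXT NOT NULL,
    ts REAL NOT NULL,
    PRIMARY KEY (project_id, target, kind, revision)
);
CREATE TABLE IF NOT EXISTS sessions (
    token TEXT PRIMARY KEY,
    payload TEXT NOT NULL,
    created REAL NOT NULL
);
CREATE TABLE IF NOT EXISTS auth_tokens (
    token TEXT PRIMARY KEY,
    user_id TEXT NOT NULL REFERENCES users(user_id) ON DELETE CASCADE,
    created REAL NOT NULL
);
"""


class AuthorizationError(PermissionError):
    pass


class ConflictError(ValueError):
    pass


@dataclass(frozen=True)
class Annotation:
    target: str
    kind: str
    value: str
    author: str
    timestamp: float
    revision: int


def _hash_credential(secret: str, salt: bytes) -> bytes:
    return hashlib.pbkdf2_hmac("sha256", secret.encode(), salt, 100_000)


class CollabStore:
    def __init__(self, path: str = ":memory:"):
        self.path = path
        # the WSGI server handles requests on worker threads; sqlite's own
        # locking serializes our short single-statement transactions
        self._db = sqlite3.connect(path, check_same_thread=False)
        self._db.execute("PRAGMA foreign_keys = ON")
        self._db.executescript(_SCHEMA)
        self._db.commit()

    def close(self):
        self._db.close()

    # -- users / auth ------------------------------------------------------

    def add_user(self, user_id: str, name: str, secret: str):
        salt = secrets.token_bytes(16)
        try:
            self._db.execute(
                "INSERT INTO users VALUES (?,?,?,?)",
                (user_id, name, salt, _hash_credential(secret, salt)),
            )
        except sqlite3.IntegrityError:
            raise ConflictError(f"user {user_id!r} already exists")
        self._db.commit()

    def authenticate(self, user_id: str, secret: str) -> str:
        row = self._db.execute(
            "SELECT salt, credential_hash FROM users WHERE user_id=?", (user_id,)
        ).fetchone()
        if row is None or not hmac.compare_digest(
            _hash_credential(secret, row[0]), row[1]
        ):
            raise AuthorizationError("bad credentials")
        token = secrets.token_urlsafe(24)
        self._db.execute(
            "INSERT INTO auth_tokens VALUES (?,?,?)", (token, user_id, time.time())
        )
        self._db.commit()
        return token

    def user_for_token(self, token: str) -> str:
        row = self._db.execute(
            "SELECT user_id FROM auth_tokens WHERE token=?", (token,)
        ).fetchone()
        if row is None:
            raise AuthorizationError("unknown token")
        return row[0]

    def role_of(self, project_id: str, user_id: str) -> Optional[str]:
        row = self._db.execute(
            "SELECT role FROM roles WHERE project_id=? AND user_id=?",
            (project_id, user_id),
        ).fetchone()
        return row[0] if row else None

    def _require(self, project_id: str, user_id: str, allowed: Sequence[str]):
        role = self.role_of(project_id, user_id)
        if role not in allowed:
            raise AuthorizationError(
                f"user {user_id!r} has role {role!r} on {project_id!r}; "
                f"needs one of {list(allowed)}"
            )

    # -- projects ----------------------------------------------------------

    def create_project(
        self, project_id: str, name: str, owner: str, species: str = "", assembly: str = ""
    ):
        if self._db.execute(
            "SELECT 1 FROM users WHERE user_id=?", (owner,)
        ).fetchone() is None:
            raise KeyError(f"unknown user {owner!r}")
        try:
            self._db.execute(
                "INSERT INTO projects VALUES (?,?,?,?)",
                (project_id, name, species, assembly),
            )
        except sqlite3.IntegrityError:
            raise ConflictError(f"project {project_id!r} already exists")
        self._db.execute(
            "INSERT INTO roles VALUES (?,?,?)", (project_id, owner, "admin")
        )
        self._db.commit()

    def delete_project(self, project_id: str, caller: str):
        self._require(project_id, caller, ("admin",))
        self._db.execute("DELETE FROM projects WHERE project_id=?", (project_id,))
        self._db.commit()

    def list_projects(self) -> List[tuple]:
        return self._db.execute(
            "SELECT project_id, name, species, assembly FROM projects ORDER BY project_id"
        ).fetchall()

    def set_role(self, project_id: str, caller: str, user_id: str, role: str):
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        self._require(project_id, caller, ("admin",))
        # never demote the last admin
        if role != "admin":
            admins = [
                u
                for (u,) in self._db.execute(
                    "SELECT user_id FROM roles WHERE project_id=? AND role='admin'",
                    (project_id,),
                )
            ]
            if admins == [user_id]:
                raise ConflictError("cannot demote the last admin")
        self._db.execute(
            "INSERT INTO roles VALUES (?,?,?) "
            "ON CONFLICT(project_id, user_id) DO UPDATE SET role=excluded.role",
            (project_id, user_id, role),
        )
        self._db.commit()

    # -- datasets ----------------------------------------------------------

    def add_dataset(
        self,
        project_id: str,
        caller: str,
        dataset_id: str,
        kind: str,
        format: str = "",
        path: str = "",
        group: str = "",
    ):
        self._require(project_id, caller, ("admin", "editor"))
        try:
            self._db.execute(
                "INSERT INTO datasets VALUES (?,?,?,?,?,?)",
                (dataset_id, project_id, kind, format, path, group),
            )
        except sqlite3.IntegrityError:
            raise ConflictError(f"dataset {dataset_id!r} already exists")
        self._db.commit()

    def batch_add_tracks(
        self, project_id: str, caller: str, items: Sequence[Tuple[str, str, str]], opener
    ) -> List[dict]:
        """Add many tracks; each item is (dataset_id, format, path).

        Every item is attempted independently; per-item success/failure is
        reported rather than aborting the batch.
        """
        self._require(project_id, caller, ("admin", "editor"))
        report = []
        for dataset_id, fmt, path in items:
            try:
                opener(path, fmt)
                self.add_dataset(project_id, caller, dataset_id, "track", fmt, path)
                report.append({"dataset_id": dataset_id, "ok": True})
            except Exception as e:
                report.append({"dataset_id": dataset_id, "ok": False, "error": str(e)})
        return report

    def list_datasets(self, project_id: str) -> List[tuple]:
        return self._db.execute(
            "SELECT dataset_id, kind, format, path, grp FROM datasets "
            "WHERE project_id=? ORDER BY dataset_id",
            (project_id,),
        ).fetchall()

    def dataset_project(self, dataset_id: str) -> Optional[str]:
        row = self._db.execute(
            "SELECT project_id FROM datasets WHERE dataset_id=?", (dataset_id,)
        ).fetchone()
        return row[0] if row else None

    # -- annotations -------------------------------------------------------

    def annotate(
        self, project_id: str, caller: str, target: str, kind: str, value: str
    ) -> int:
        """Append a new revision for (target, kind); returns the revision."""
        self._require(project_id, caller, ("admin", "editor"))
        if self._db.execute(
            "SELECT 1 FROM projects WHERE project_id=?", (project_id,)
        ).fetchone() is None:
            raise KeyError(f"unknown project {project_id!r}")
        row = self._db.execute(
            "SELECT MAX(revision) FROM annotations WHERE project_id=? AND target=? AND kind=?",
            (project_id, target, kind),
        ).fetchone()
        revision = (row[0] or 0) + 1
        self._db.execute(
            "INSERT INTO annotations VALUES (?,?,?,?,?,?,?)",
            (project_id, target, kind, revision, value, caller, time.time()),
        )
        self._db.commit()
        return revision

    def latest_annotation(self, project_id: str, target: str, kind: str) -> Optional[Annotation]:
        row = self._db.execute(
            "SELECT value, author, ts, revision FROM annotations "
            "WHERE project_id=? AND target=? AND kind=? ORDER BY revision DESC LIMIT 1",
            (project_id, target, kind),
        ).fetchone()
        if row is None:
            return None
        return Annotation(target, kind, row[0], row[1], row[2], row[3])

    def annotation_history(self, project_id: str, target: str, kind: str) -> List[Annotation]:
        rows = self._db.execute(
            "SELECT value, author, ts, revision FROM annotations "
            "WHERE project_id=? AND target=? AND kind=? ORDER BY revision",
            (project_id, target, kind),
        ).fetchall()
        return [Annotation(target, kind, v, a, t, r) for v, a, t, r in rows]

    # -- sessions ----------------------------------------------------------

    def store_session(self, payload: str) -> str:
        token = secrets.token_urlsafe(12)
        self._db.execute(
            "INSERT INTO sessions VALUES (?,?,?)", (token, payload, time.time())
        )
        self._db.commit()
        return token

    def fetch_session(self, token: str) -> str:
        row = self._db.execute(
            "SELECT payload FROM sessions WHERE token=?", (token,)
        ).fetchone()
        if row is None:
            raise KeyError(f"unknown session token {token!r}")
        return row[0]
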