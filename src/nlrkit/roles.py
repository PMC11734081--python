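"""Domain-role configuration.

A *role* is an architectural slot in an NLR protein: the NB-ARC
nucleotide-binding domain (``N``), the four tracked leucine-rich-repeat
entries (``L1``-``L4``), the N-terminal coiled-coil (``C``) and the TIR
domain (``T``).  Each role is backed by a set of InterPro accessions; a
protein occupies a role when any of its InterPro hits falls in that set.

The default map ships with the package (``data/roles.yaml``).  N and
L1-L4 are fixed by the mining protocol; C and T have no single canonical
InterPro entry and are user-overridable, so every classification records
the hash of the map in force.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

from .errors import ValidationError

IPR_PATTERN = re.compile(r"^IPR\d{6}$")

#: Roles that must be non-empty (the mining inputs).
REQUIRED_ROLES = ("N", "L1", "L2", "L3", "L4")

#: All recognised roles, in canonical order.
ALL_ROLES = ("N", "L1", "L2", "L3", "L4", "C", "T")

#: Roles used for candidate mining and co-occurrence profiling.
TRACKED_ROLES = ("N", "L1", "L2", "L3", "L4")


@dataclass(frozen=True)
class DomainRoleConfig:
    """Mapping from architectural roles to sets of InterPro accessions.

    Role sets must be pairwise disjoint so that a single accession never
    asserts two different roles.
    """

    role_map: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = {}
        for role in ALL_ROLES:
            accs = frozenset(self.role_map.get(role, ()))
            for acc in accs:
                if not IPR_PATTERN.match(acc):
                    raise ValidationError(
                        f"role {role}: {acc!r} is not an InterPro accession"
                    )
            normalized[role] = accs
        extra = set(self.role_map) - set(ALL_ROLES)
        if extra:
            raise ValidationError(f"unknown roles in config: {sorted(extra)}")
        for role in REQUIRED_ROLES:
            if not normalized[role]:
                raise ValidationError(f"role {role} must be non-empty")
        seen: dict = {}
        for role, accs in normalized.items():
            for acc in accs:
                if acc in seen:
                    raise ValidationError(
                        f"accession {acc} assigned to both {seen[acc]} and {role}"
                    )
                seen[acc] = role
        object.__setattr__(self, "role_map", normalized)
        object.__setattr__(self, "_acc_to_role", seen)

    @classmethod
    def default(cls) -> "DomainRoleConfig":
        """The role map shipped with the package."""
        with resources.files("nlrkit.data").joinpath("roles.yaml").open() as fh:
            return cls.from_yaml_stream(fh)

    @classmethod
    def from_yaml(cls, path) -> "DomainRoleConfig":
        with open(path) as fh:
            return cls.from_yaml_stream(fh)

    @classmethod
    def from_yaml_stream(cls, stream) -> "DomainRoleConfig":
        doc = yaml.safe_load(stream)
        if not isinstance(doc, dict) or "roles" not in doc:
            raise ValidationError("role-map YAML must contain a top-level 'roles' mapping")
        return cls({r: frozenset(a) for r, a in doc["roles"].items()})

    def to_yaml(self, path) -> None:
        doc = {"roles": {r: sorted(self.role_map[r]) for r in ALL_ROLES}}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    def role_of(self, accession: str) -> Optional[str]:
        """Role asserted by *accession*, or None if untracked."""
        return self._acc_to_role.get(accession)

    def accessions(self, roles: Iterable[str]) -> frozenset:
        out: set = set()
        for role in roles:
            out |= self.role_map[role]
        return frozenset(out)

    @property
    def tracked_accessions(self) -> frozenset:
        """Accessions used for candidate mining (roles N, L1-L4)."""
        return self.accessions(TRACKED_ROLES)

    def config_hash(self) -> str:
        """Stable short hash of the role map, reported with classifications."""
        canon = json.dumps(
            {r: sorted(self.role_map[r]) for r in ALL_ROLES}, sort_keys=True
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
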