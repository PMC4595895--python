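# sbmlkit

An SBML Level 3 toolkit for Python: a typed in-memory document model with
canonical reading and writing, an infix ↔ content-MathML math subsystem,
unit-of-measure algebra, identifier-namespace management, and support for
the Level 3 packages used in practice for multi-formalism modeling —
*flux balance constraints* (fbc), *qualitative models* (qual),
*hierarchical model composition* (comp), *groups* and *arrays* — including
flattening of hierarchical and arrayed models down to plain core
constructs.

It is aimed at tool builders in systems biology who need to read, check,
transform and re-emit SBML models reproducibly: the writer has exactly one
canonical dialect, the validator's reports are byte-stable, and the
bundled fixture generator produces valid random documents from an explicit
seed, so pipelines built on sbmlkit can be tested offline end to end.

## What it implements

- **Document model** (`sbmlkit.core`): every core Level 3 construct
  (function definitions, units, compartments, species, parameters, rules,
  constraints, reactions with kinetic laws and local parameters, events)
  as plain dataclasses sharing the SBase slots (`metaid`, `sboTerm`,
  notes/annotation kept as generic XML subtrees, transient user objects).
  Identifier syntax is enforced at assignment time.
- **I/O** (`sbmlkit.io`): whole-document reader and canonical writer.
  Elements of unsupported packages survive round trips structurally
  unchanged; a required-but-unsupported package flags the document rather
  than aborting the read.
- **Math** (`sbmlkit.math`): the Level 3 infix grammar (precedence
  `or < and < not < relational < + - < * / % < unary minus < ^`,
  with `^` right-associative and `-2^2 = -(2^2)`), a serializer emitting
  minimal parentheses, a content-MathML bridge, an IEEE-754 evaluator
  with function-definition beta-reduction, and capture-avoiding
  substitution. `a % b` is lowered on parse to an equivalent
  floor/ceiling piecewise, since the L3V1 MathML subset has no remainder
  operator.
- **Units** (`sbmlkit.units`): canonicalization to SI base kinds with
  exact rational exponents, the multiplicative algebra
  (multiply/divide/power), *equivalent* vs *identical* comparison, and
  derivation of units for whole expressions with warning diagnostics for
  inconsistent sums.
- **Identifiers** (`sbmlkit.identifiers`): scoped namespaces (model SIds,
  unit ids, per-kinetic-law locals, per-model ports, per-element array
  dimensions), collected conflict detection, deterministic fresh-id
  generation.
- **Packages**: GPR association trees, strict-mode checks and sparse
  stoichiometric-matrix export (`sbmlkit.fbc`); synchronous execution and
  state-space/attractor analysis of logical models (`sbmlkit.qual`);
  submodel instantiation, port/reference resolution and flattening
  (`sbmlkit.comp`); dimension/index validation and array expansion
  (`sbmlkit.arrays`); element groups (`sbmlkit.core.Group`).
- **Validator** (`sbmlkit.validator`): identifier, reference, math, unit
  and package rules aggregated into a deterministic issue list with
  stable rule ids.
- **Fixtures** (`sbmlkit.fixtures`): seeded random documents and a
  hand-written golden corpus, including deliberately broken documents
  with their expected diagnostics.

## Worked example

```python
from sbmlkit import io, comp, qual, validator
from sbmlkit.fixtures import golden_document
from sbmlkit.math import parse_infix, evaluate, to_infix

# parse and evaluate a kinetic-law formula
node = parse_infix("piecewise(-x, x < 0, x) + 2^3^2")
print(to_infix(node))        # piecewise(-x, x < 0, x) + 2^3^2
print(evaluate(node, {"x": -3}))   # 515.0  (|-3| + 2^(3^2))

# flatten a two-level hierarchical model
doc = io.read(golden_document("comp_two_level.xml"))
flat = comp.flatten(doc)
print([p.id for p in flat.model.parameters])
# ['p', 'wt', 'sub1__wm', 'sub1__sub2__kq', 'sub1__sub2__wl']

# run a Boolean toggle switch and find its attractors
toggle = io.read(golden_document("qual_toggle.xml")).model
att = qual.attractors(qual.state_space(toggle))
print([sorted(a) for a in att])
# [[(0, 0), (1, 1)], [(0, 1)], [(1, 0)]]
```

The flattened parameter list shows every submodel identifier under its
`<submodelId>__` prefix, with the replaced parameter unified to the
parent's `p`; the toggle's state space has the two antagonistic fixed
points (A on / B off and the reverse) plus the period-2 oscillation of
the simultaneous-update scheme.

The same operations are available from the shell:

```bash
sbmlkit validate model.xml --tsv report.tsv
sbmlkit flatten --comp --arrays nested.xml -o flat.xml
sbmlkit fbc matrix model.xml --mtx S.mtx
sbmlkit qual statespace toggle.xml
sbmlkit fixtures generate --seed 1 --count 5 --fbc -o out/
```

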