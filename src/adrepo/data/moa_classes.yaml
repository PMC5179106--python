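# Mode-of-action vocabulary partitioned by pharmacological direction.
# "inhibiting" modes oppose a gain-of-function target; "activating" modes
# restore a loss-of-function target; "neutral" modes carry no direction, so
# mechanistic compatibility cannot be judged from them.
inhibiting:
  - inhibitor
  - antagonist
  - antibody
  - blocker
  - suppressor
activating:
  - agonist
  - activator
  - inducer
  - stimulator
neutral:
  - substrate
  - modulator
  - binder
  - cofactor
  - unknown
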