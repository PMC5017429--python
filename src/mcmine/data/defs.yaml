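- class: OfficeWork
  activities:
  - Sitting
  locations:
  - Office
  emotions: ANY
  priority: 1
- class: HavingMeal
  activities:
  - Eating
  locations:
  - Home
  - Restaurant
  emotions: ANY
  priority: 2
- class: Housework
  activities:
  - Sweeping
  locations:
  - Home
  emotions: ANY
  priority: 3
- class: Exercising
  activities:
  - Running
  - Stretching
  - Walking
  locations:
  - Gym
  emotions: ANY
  priority: 4
- class: Exercising
  activities:
  - Running
  locations: ANY
  emotions: ANY
  priority: 5
- class: Inactivity
  activities:
  - LyingDown
  - Sitting
  - Standing
  locations: ANY
  emotions: ANY
  priority: 6
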