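# Demonstration lexicons for the DSM-5 criterion rule engine.
# One phrase per line; [sections] name the lexicons.

[negation]
not
no
never
doesn't
does not
did not
won't
cannot
unable

[poor_quality]
poor
limited
little
weak

[a1_disinterest]
indifferent to
pragmatic language
disinterested in

[a1_initiate]
initiate
initiating

[name_response]
respond to his name
respond to her name
answer to his name
answer to her name
respond when called

[eye_contact]
eye contact

[gestures]
gestures
gesturing

[facial_expressions]
facial expressions

[play_verb]
play
plays
played
playing

[solitary]
by himself
by herself
alone

[friend_difficulty]
difficulty making friends
no friends
few friends

[peer_interest]
interest in other children
interest in peers
interested in peers

[repetition]
repeat
repeats
repeating
repetitive
echolalia

[motor_stereotypy]
flaps his hands
flaps her hands
hand flapping
flapping
lines up his toys
lines up her toys
rocks back and forth

[sameness]
routine
sameness
difficulty adapting
schedule changes
transitions

[fixation]
fixated
fixation
preoccupied
obsessed
intense interest

[same_things]
the same things over and over
same things over and over

[sensory]
sensory
sensitive to
covers his ears
covers her ears
covering his ears
covering her ears
textures

[group_play]
with peers
with other children
with friends
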