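# Demonstration rules: rule_id CRITERION : slots [!guard_lexicon]
# Slots: bare word = literal token, "quoted" = literal phrase,
#        @name = lexicon phrase, ~N = gap of up to N tokens.

# A1 — deficits in social-emotional reciprocity
A1_disinterest      A1 : @a1_disinterest
A1_no_initiation    A1 : @negation ~3 @a1_initiate
A1_name_response    A1 : @negation ~2 @name_response

# A2 — deficits in nonverbal communicative behaviors
A2_no_eye_contact   A2 : @negation ~4 @eye_contact
A2_poor_eye_contact A2 : @poor_quality ~1 @eye_contact
A2_no_gestures      A2 : @negation ~2 @gestures
A2_flat_affect      A2 : @poor_quality ~1 @facial_expressions

# A3 — deficits in developing and maintaining relationships
A3_solitary_play    A3 : @play_verb ~2 @solitary !group_play
A3_friendships      A3 : @friend_difficulty
A3_no_peer_interest A3 : @negation ~1 @peer_interest

# B1 — stereotyped or repetitive movements / speech
B1_repetition       B1 : @repetition
B1_motor            B1 : @motor_stereotypy

# B2 — insistence on sameness
B2_sameness         B2 : @sameness
B2_upset_routine    B2 : "upset if the routine"

# B3 — highly restricted, fixated interests
B3_fixation         B3 : @fixation
B3_same_things      B3 : @same_things

# B4 — hyper- or hyporeactivity to sensory input
B4_sensory          B4 : @sensory
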